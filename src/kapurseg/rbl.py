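"""Opposition- and rotation-based learning, and the GTORBL optimizer.

Opposition-based learning (OBL) evaluates the mirror image
``a + b - z`` of each candidate within a box ``[a, b]`` on the premise
that either a point or its opposite tends to be closer to the optimum.
Rotation-based learning (RBL) generalizes this: a candidate ``T_i`` in
``[a_i, b_i]`` is lifted to the circle of diameter ``b_i - a_i`` and
rotated about the interval centre by a deflection angle ``phi``::

    u_i  = T_i - (a_i + b_i)/2
    v_i  = sqrt((T_i - a_i)(b_i - T_i))
    T*_i = (a_i + b_i)/2 + u_i cos(phi) - v_i sin(phi)

``phi = 180`` degrees recovers OBL exactly and ``phi = 0`` is the
identity.  The angle is drawn per individual as
``phi = phi0 * Normal(1, sigma)`` (defaults phi0 = 180 deg,
sigma = 0.25, so draws land primarily inside [90, 270] degrees).

GTORBL couples RBL to GTO: the initial population is augmented with its
rotated image and the best N of the 2N are kept; after every GTO
generation, with probability ``p_gj`` (the generation-jumping rate) the
current population is rotated over its own per-dimension bounding box,
evaluated, and again truncated to the best N.  Elitism holds because
truncation never discards the incumbent best.  Asymptotic cost is the
same Theta(T N D) time / Theta(N D) space as plain GTO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gto import (Bounds, GTOParams, OptimizerResult, _Evaluator,
                  _init_population, gto_iteration)


@dataclass
class RBLParams:
    """Rotation-based-learning parameters.

    phi0 : basic deflection angle in degrees (default 180, the OBL case).
    sigma : spread of the Gaussian angle multiplier (default 0.25).
    p_gj : generation-jumping rate, the per-generation probability of a
        rotation jump (default 0.3).
    """

    phi0: float = 180.0
    sigma: float = 0.25
    p_gj: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.phi0 < 360.0:
            raise ValueError("phi0 must be in (0, 360) degrees")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.p_gj < 1.0:
            raise ValueError("p_gj must be in [0, 1)")


@dataclass
class RotationFrame:
    """Per-dimension rotation area ``[a, b]`` with centre B and radius r."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=np.float64))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=np.float64))
        if self.a.shape != self.b.shape or np.any(self.a > self.b):
            raise ValueError("frame requires a <= b elementwise")

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)

    @property
    def radius(self) -> np.ndarray:
        return 0.5 * (self.b - self.a)


def opposite_point(z: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """OBL mirror ``a + b - z``; `z` is clamped into ``[a, b]`` first."""
    z = np.clip(np.asarray(z, dtype=np.float64), a, b)
    return np.asarray(a) + np.asarray(b) - z


def rotation_point(t: np.ndarray, frame: RotationFrame, phi_deg: float) -> np.ndarray:
    """Rotate `t` about the frame centre by `phi_deg` degrees.

    Degenerate dimensions (``a_i == b_i``) map to ``a_i``; the result is
    clamped back into the frame.
    """
    a, b = frame.a, frame.b
    t = np.clip(np.asarray(t, dtype=np.float64), a, b)
    phi = np.deg2rad(phi_deg)
    u = t - frame.center
    v = np.sqrt(np.maximum((t - a) * (b - t), 0.0))
    out = frame.center + u * np.cos(phi) - v * np.sin(phi)
    out = np.where(a == b, a, out)
    return np.clip(out, a, b)


def sample_deflection_angle(params: RBLParams, rng: np.random.Generator) -> float:
    """One deflection angle phi = phi0 * Normal(1, sigma), in degrees."""
    return float(params.phi0 * rng.normal(1.0, params.sigma))


def rotated_population(positions: np.ndarray, params: RBLParams,
                       rng: np.random.Generator,
                       angles: np.ndarray | None = None) -> np.ndarray:
    """Rotate every individual over the population's own bounding box.

    The rotation area is the per-dimension min/max of `positions`; each
    individual gets its own sampled deflection angle (pass `angles` to
    override, e.g. a constant 180 degrees to reproduce plain OBL).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    frame = RotationFrame(positions.min(axis=0), positions.max(axis=0))
    out = np.empty_like(positions)
    for i, t in enumerate(positions):
        phi = angles[i] if angles is not None else sample_deflection_angle(params, rng)
        out[i] = rotation_point(t, frame, phi)
    return out


def _keep_best_n(X: np.ndarray, fit: np.ndarray, X2: np.ndarray,
                 fit2: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Best n of the merged 2n, sorted by fitness, stable on ties."""
    all_x = np.vstack([X, X2])
    all_f = np.concatenate([fit, fit2])
    order = np.argsort(-all_f, kind="stable")[:n]
    return all_x[order].copy(), all_f[order].copy()


def gtorbl_optimize(objective, bounds: Bounds, params: GTOParams | None = None,
                    rbl_params: RBLParams | None = None,
                    rng: np.random.Generator | int | None = None,
                    init_rotation: bool = True) -> OptimizerResult:
    """Maximize `objective` with the RBL-enhanced gorilla troops optimizer.

    Same contract as :func:`kapurseg.gto.gto_optimize`.  With
    ``init_rotation=False`` and ``p_gj=0`` the trajectory is identical to
    plain GTO under the same seed.
    """
    params = params or GTOParams()
    rbl_params = rbl_params or RBLParams()
    rng = np.random.default_rng(rng)
    evaluator = _Evaluator(objective)

    X = _init_population(bounds, params.n_agents, rng)
    fit = evaluator(X)
    if init_rotation:
        Xr = rotated_population(X, rbl_params, rng)
        X, fit = _keep_best_n(X, fit, Xr, evaluator(Xr), params.n_agents)

    best_i = int(np.argmax(fit))
    best_x, best_f = X[best_i].copy(), float(fit[best_i])
    trace = [(evaluator.n_evals, best_f)]

    for t in range(1, params.max_iters + 1):
        t_norm = t / params.max_iters
        gto_iteration(X, fit, t_norm, params, bounds, evaluator, rng)
        # generation jumping: rotate the whole troop with rate p_gj
        if rbl_params.p_gj > 0 and rng.random() < rbl_params.p_gj:
            Xr = rotated_population(X, rbl_params, rng)
            X, fit = _keep_best_n(X, fit, Xr, evaluator(Xr), params.n_agents)
        it_best = float(fit[int(np.argmax(fit))])
        if it_best > best_f:
            best_f = it_best
            best_x = X[int(np.argmax(fit))].copy()
        trace.append((evaluator.n_evals, best_f))

    return OptimizerResult(best_x, best_f, trace)
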