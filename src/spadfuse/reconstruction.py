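"""Convex fusion of the SPAD cube with the CCD image.

The high-resolution transient cube ``i_HR`` is the minimizer of the
five-term convex program

    min_i  ||A_tau i - d||_2 + alpha ||T i - c||_2
           + beta ||K_h i - K_l d||_2 + gamma ||i||_1 + delta ||grad_2D i||_1
    s.t.   i >= 0

where ``A_tau`` is the per-bin measurement operator, ``T`` integrates the
cube over time, and ``K_h``/``K_l`` integrate the high/low-resolution cubes
over space (the temporal-histogram prior: the reconstruction's photon
arrival-time distribution must match the measured one).  The L2 norms are
UNSQUARED, which makes every data term a second-order-cone atom.

Both spatial-integration histograms are brought to approximately unit mass
before differencing — ``K_h i`` is divided by the total of the (rescaled)
CCD image, a constant, and ``K_l d`` by the total of ``d`` — so the
``beta`` weight is scale-free while the term stays linear in ``i`` (and
hence the program convex).

Solvers
-------
``pdhg`` (default)
    Chambolle–Pock primal–dual hybrid gradient.  The unsquared norms are
    handled exactly: each data term's dual update is a Euclidean-ball
    projection, the TV dual an L-infinity ball clip, and with ``i >= 0``
    the L1 penalty reduces to a linear term absorbed into the primal prox.
    Deterministic: initialized at the adjoint back-projection ``A^T d``.
``lbfgs``
    Bound-constrained L-BFGS on a smoothed surrogate (each norm replaced by
    ``sqrt(||.||^2 + eps^2)``).  Kept as an independent route for
    cross-checking the primal–dual solution.

An optional squared-L2 variant of the data terms is available behind
``squared=True``; it is a deliberate deviation from the cone form, useful
for speed comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .forward_model import FusionGeometry, _adjoint_raw, _forward_raw
from .types import HIGH, LOW, IntensityImage, TransientCube

__all__ = [
    "RegularizationWeights",
    "ReconstructionResult",
    "WEIGHT_PRESETS",
    "temporal_integrate",
    "temporal_histogram",
    "grad2d",
    "div2d",
    "tv2d",
    "Tv2dOperator",
    "rescale_ccd",
    "objective_value",
    "reconstruct",
]


@dataclass(frozen=True)
class RegularizationWeights:
    """Weights of the five-term objective.

    alpha — CCD-consistency; beta — temporal-histogram similarity;
    gamma — L1 sparsity; delta — 2-D total variation.  All >= 0.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Published parameter presets.  ``lidar`` was used for the depth-imaging
#: scenes, ``flim`` for the lifetime-imaging scenes.
WEIGHT_PRESETS: dict[str, RegularizationWeights] = {
    "lidar": RegularizationWeights(alpha=1.0, beta=1e-4, gamma=1e-2, delta=0.0),
    "flim": RegularizationWeights(alpha=1.0, beta=1e-3, gamma=1e-7, delta=1e-5),
}


@dataclass
class ReconstructionResult:
    """Outcome of :func:`reconstruct`."""

    cube: TransientCube
    objective: float
    solver_status: str
    n_iter: int
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary linear pieces

def temporal_integrate(cube: TransientCube) -> IntensityImage:
    """T: per-pixel sum over time bins.  Total counts are conserved."""
    return IntensityImage(cube.values.sum(axis=0), grid=cube.grid)


def temporal_histogram(cube: TransientCube, normalize: bool = False) -> np.ndarray:
    """K: per-bin sum over all spatial pixels.

    With ``normalize=True`` the histogram is scaled to unit mass (an
    all-zero cube yields the zero vector).
    """
    h = cube.values.sum(axis=(1, 2))
    if normalize:
        s = h.sum()
        if s > 0:
            h = h / s
    return h


def grad2d(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward finite differences along rows and columns of each frame."""
    gr = frames[..., 1:, :] - frames[..., :-1, :]
    gc = frames[..., :, 1:] - frames[..., :, :-1]
    return gr, gc


def div2d(gr: np.ndarray, gc: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Adjoint of :func:`grad2d` (negative divergence)."""
    out = np.zeros(shape)
    out[..., 1:, :] += gr
    out[..., :-1, :] -= gr
    out[..., :, 1:] += gc
    out[..., :, :-1] -= gc
    return out


def tv2d(frames: np.ndarray) -> float:
    """Anisotropic 2-D total variation summed over frames."""
    gr, gc = grad2d(frames)
    return float(np.abs(gr).sum() + np.abs(gc).sum())


class Tv2dOperator:
    """The stacked finite-difference operator on M x N frames.

    ``matvec`` maps a row-major vectorized frame to the concatenation of
    its row differences and column differences; ``rmatvec`` is the adjoint.
    """

    def __init__(self, M: int, N: int):
        if M < 2 or N < 2:
            raise ValueError("TV operator needs M, N >= 2")
        self.M, self.N = M, N
        self.shape = ((M - 1) * N + M * (N - 1), M * N)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        frame = np.asarray(x).reshape(self.M, self.N)
        gr, gc = grad2d(frame)
        return np.concatenate([gr.ravel(), gc.ravel()])

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        k = (self.M - 1) * self.N
        gr = np.asarray(y)[:k].reshape(self.M - 1, self.N)
        gc = np.asarray(y)[k:].reshape(self.M, self.N - 1)
        return div2d(gr, gc, (self.M, self.N)).ravel()


def rescale_ccd(
    c: IntensityImage, d: TransientCube, geometry: FusionGeometry
) -> IntensityImage:
    """Bring the CCD image to the SPAD photon-count scale.

    Returns ``s * c`` with the scalar ``s`` chosen so that the total of
    ``A (s c)`` equals the total counts in ``d``.  The two sensors have
    independent gains and exposure times; this deterministic rescale is the
    only cross-calibration the objective assumes.
    """
    if c.grid != HIGH:
        raise ValueError("CCD image must be on the high-res grid")
    fwd_total = float(_forward_raw(c.values, geometry).sum())
    if fwd_total <= 0:
        raise ValueError("cannot rescale a CCD image with zero projected total")
    s = d.total() / fwd_total
    return IntensityImage(c.values * s, grid=HIGH)


# ---------------------------------------------------------------------------
# Objective

def _hist_scales(d_total: float, c_total: float) -> tuple[float, float]:
    return (d_total if d_total > 0 else 1.0, c_total if c_total > 0 else 1.0)


def _norm(x: np.ndarray) -> float:
    return float(np.linalg.norm(x.ravel()))


def objective_value(
    i: TransientCube,
    d: TransientCube,
    c: IntensityImage,
    geometry: FusionGeometry,
    weights: RegularizationWeights,
    squared: bool = False,
) -> float:
    """Evaluate the five-term objective at ``i``.

    ``c`` must already be on the SPAD count scale (see :func:`rescale_ccd`).
    """
    x = i.values
    if x.shape != (d.n_bins, geometry.M, geometry.N):
        raise ValueError(
            f"cube shape {x.shape} inconsistent with geometry/measurement "
            f"({d.n_bins},{geometry.M},{geometry.N})"
        )
    if d.values.shape[1:] != geometry.low_shape:
        raise ValueError("measurement shape inconsistent with geometry")
    if c.values.shape != geometry.high_shape:
        raise ValueError("CCD shape inconsistent with geometry")
    s_d, s_c = _hist_scales(d.total(), c.total())

    r_data = _norm(_forward_raw(x, geometry) - d.values)
    r_ccd = _norm(x.sum(axis=0) - c.values)
    r_hist = _norm(x.sum(axis=(1, 2)) / s_c - d.values.sum(axis=(1, 2)) / s_d)
    if squared:
        r_data, r_ccd, r_hist = r_data**2, r_ccd**2, r_hist**2
    return (
        r_data
        + weights.alpha * r_ccd
        + weights.beta * r_hist
        + weights.gamma * float(np.abs(x).sum())
        + weights.delta * tv2d(x)
    )


# ---------------------------------------------------------------------------
# PDHG solver

def _power_iteration_norm(apply_ktk, shape: tuple[int, ...], n_iter: int = 30) -> float:
    """Largest singular value of K via power iteration on K^T K
    (deterministic start)."""
    x = np.ones(shape) + np.linspace(0.0, 1.0, int(np.prod(shape))).reshape(shape)
    x /= _norm(x)
    lam = 1.0
    for _ in range(n_iter):
        y = apply_ktk(x)
        lam = _norm(y)
        if lam == 0:
            return 1.0
        x = y / lam
    return float(np.sqrt(lam))


def _proj_l2_ball(v: np.ndarray, radius: float) -> np.ndarray:
    nrm = _norm(v)
    if nrm <= radius or nrm == 0:
        return v
    return v * (radius / nrm)


def _prox_conj_l2(y: np.ndarray, b: np.ndarray, w: float, sigma: float, squared: bool) -> np.ndarray:
    # prox of the convex conjugate of z -> w * ||z - b||_2 (or squared)
    if squared:
        return (y - sigma * b) / (1.0 + sigma / (2.0 * w))
    return _proj_l2_ball(y - sigma * b, w)


def _solve_pdhg(
    d_arr: np.ndarray,
    c_arr: np.ndarray,
    geometry: FusionGeometry,
    weights: RegularizationWeights,
    *,
    max_iter: int,
    tol: float,
    squared: bool,
    verbose: bool,
    step_ratio: float | None = None,
    discrepancy: float | None = None,
) -> tuple[np.ndarray, str, int, dict]:
    tau_bins = d_arr.shape[0]
    shape = (tau_bins, geometry.M, geometry.N)
    s_d, s_c = _hist_scales(float(d_arr.sum()), float(c_arr.sum()))
    hist_target = d_arr.sum(axis=(1, 2)) / s_d
    a, b, g, dl = weights.alpha, weights.beta, weights.gamma, weights.delta

    def apply_ktk(x: np.ndarray) -> np.ndarray:
        out = _adjoint_raw(_forward_raw(x, geometry), geometry)
        if a > 0:
            out = out + np.broadcast_to(x.sum(axis=0), shape)
        if b > 0:
            out = out + (x.sum(axis=(1, 2)) / s_c**2)[:, None, None]
        if dl > 0:
            out = out + div2d(*grad2d(x), shape)
        return out

    L = _power_iteration_norm(apply_ktk, shape) * 1.01

    x = np.maximum(_adjoint_raw(d_arr, geometry), 0.0)
    # Unbalanced steps: the dual variables live on unit-order balls (radii
    # are the term weights) while the primal lives on the photon-count
    # scale, so the primal step is scaled up by that ratio.
    if step_ratio is None:
        step_ratio = 1.0 / max(_norm(x), 1.0)
    sp = 0.999 * step_ratio / L
    tp = 0.95 / (step_ratio * L)
    x_bar = x.copy()
    y1 = np.zeros_like(d_arr)
    y2 = np.zeros(geometry.high_shape) if a > 0 else None
    y3 = np.zeros(tau_bins) if b > 0 else None
    y4 = (
        (np.zeros((tau_bins, geometry.M - 1, geometry.N)),
         np.zeros((tau_bins, geometry.M, geometry.N - 1)))
        if dl > 0
        else None
    )

    status, it = "max_iter", max_iter
    check_every = 10
    confirm = 100  # discrepancy must hold this many iterations before stopping
    stag_window, stag_rtol = 100, 2e-3
    res_history: list[tuple[int, float]] = []
    below_since: int | None = None
    for k in range(1, max_iter + 1):
        y1 = _prox_conj_l2(y1 + sp * (_forward_raw(x_bar, geometry) - d_arr), np.zeros(1), 1.0, sp, squared)
        # note: b already subtracted inside the residual above, so pass b=0
        grad_accum = _adjoint_raw(y1, geometry)
        if a > 0:
            y2 = _prox_conj_l2(y2 + sp * (x_bar.sum(axis=0) - c_arr), np.zeros(1), a, sp, squared)
            grad_accum = grad_accum + np.broadcast_to(y2, shape)
        if b > 0:
            y3 = _prox_conj_l2(
                y3 + sp * (x_bar.sum(axis=(1, 2)) / s_c - hist_target),
                np.zeros(1), b, sp, squared,
            )
            grad_accum = grad_accum + (y3 / s_c)[:, None, None]
        if dl > 0:
            gr, gc = grad2d(x_bar)
            y4 = (
                np.clip(y4[0] + sp * gr, -dl, dl),
                np.clip(y4[1] + sp * gc, -dl, dl),
            )
            grad_accum = grad_accum + div2d(y4[0], y4[1], shape)

        x_new = np.maximum(x - tp * grad_accum - tp * g, 0.0)
        x_bar = 2.0 * x_new - x

        if k % check_every == 0 or k == max_iter:
            delta_rel = _norm(x_new - x) / max(_norm(x_new), 1e-30)
            if verbose and k % (check_every * 20) == 0:
                print(f"  pdhg iter {k}: rel step {delta_rel:.3e}")
            if delta_rel < tol:
                status, it = "converged", k
                x = x_new
                break
            if discrepancy is not None:
                # Morozov stopping with a confirmation window: halt once the
                # data residual has stayed at the noise floor for `confirm`
                # iterations, or once it has stagnated above the floor
                # (beyond either point further iterations only fit shot
                # noise / reshape mass among the priors).
                rd = _norm(_forward_raw(x_new, geometry) - d_arr)
                res_history.append((k, rd))
                if rd <= discrepancy:
                    if below_since is None:
                        below_since = k
                    if k - below_since >= confirm:
                        status, it = "discrepancy", k
                        x = x_new
                        break
                else:
                    below_since = None
                    past = [r for kk, r in res_history if kk <= k - stag_window]
                    if past and (past[-1] - rd) / max(rd, 1e-30) < stag_rtol:
                        status, it = "stagnation", k
                        x = x_new
                        break
        x = x_new

    return x, status, it, {
        "operator_norm": L,
        "step_ratio": step_ratio,
        "discrepancy_target": discrepancy,
    }


# ---------------------------------------------------------------------------
# Smoothed L-BFGS-B solver (independent route)

def _solve_lbfgs(
    d_arr: np.ndarray,
    c_arr: np.ndarray,
    geometry: FusionGeometry,
    weights: RegularizationWeights,
    *,
    max_iter: int,
    tol: float,
    squared: bool,
    discrepancy: float | None = None,
) -> tuple[np.ndarray, str, int, dict]:
    tau_bins = d_arr.shape[0]
    shape = (tau_bins, geometry.M, geometry.N)
    s_d, s_c = _hist_scales(float(d_arr.sum()), float(c_arr.sum()))
    hist_target = d_arr.sum(axis=(1, 2)) / s_d
    a, b, g, dl = weights.alpha, weights.beta, weights.gamma, weights.delta
    eps = 1e-6 * max(_norm(d_arr), 1.0)

    def smooth_norm(r: np.ndarray) -> tuple[float, float]:
        n2 = float((r * r).sum())
        if squared:
            return n2, 2.0
        s = float(np.sqrt(n2 + eps * eps))
        return s, 1.0 / s

    def fun(xflat: np.ndarray) -> tuple[float, np.ndarray]:
        x = xflat.reshape(shape)
        val = 0.0
        grad = np.zeros(shape)

        r = _forward_raw(x, geometry) - d_arr
        v, dv = smooth_norm(r)
        val += v
        grad += dv * _adjoint_raw(r, geometry)

        if a > 0:
            r = x.sum(axis=0) - c_arr
            v, dv = smooth_norm(r)
            val += a * v
            grad += a * dv * np.broadcast_to(r, shape)
        if b > 0:
            r = x.sum(axis=(1, 2)) / s_c - hist_target
            v, dv = smooth_norm(r)
            val += b * v
            grad += b * dv * (r / s_c)[:, None, None]
        if g > 0:
            val += g * float(x.sum())  # x >= 0 under the bounds
            grad += g
        if dl > 0:
            gr, gc = grad2d(x)
            mr = np.sqrt(gr * gr + eps * eps)
            mc = np.sqrt(gc * gc + eps * eps)
            val += dl * float(mr.sum() + mc.sum())
            grad += dl * div2d(gr / mr, gc / mc, shape)
        return val, grad.ravel()

    x0 = np.maximum(_adjoint_raw(d_arr, geometry), 0.0).ravel()

    hit_discrepancy = False
    last_x = [x0]

    def callback(xk: np.ndarray) -> None:
        nonlocal hit_discrepancy
        last_x[0] = xk
        if discrepancy is not None:
            r = _norm(_forward_raw(xk.reshape(shape), geometry) - d_arr)
            if r <= discrepancy:
                hit_discrepancy = True
                raise StopIteration

    try:
        res = optimize.minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=optimize.Bounds(0.0, np.inf),
            callback=callback,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12, "maxcor": 20},
        )
        x, n_iter, msg = res.x, int(res.nit), str(res.message)
        status = "converged" if res.success else "limit"
    except StopIteration:
        x, n_iter, msg = last_x[0], -1, "discrepancy stop"
        status = "discrepancy"
    if hit_discrepancy:
        status = "discrepancy"
    return x.reshape(shape), status, n_iter, {"message": msg}


# ---------------------------------------------------------------------------
# Entry point

def reconstruct(
    d: TransientCube,
    c: IntensityImage,
    geometry: FusionGeometry,
    weights: RegularizationWeights,
    *,
    solver: str = "pdhg",
    max_iter: int = 3000,
    tol: float = 1e-9,
    squared: bool = False,
    rescale: bool = True,
    discrepancy: float | str | None = "auto",
    step_ratio: float | None = None,
    verbose: bool = False,
) -> ReconstructionResult:
    """Solve the fusion program for the high-resolution transient cube.

    Parameters
    ----------
    d
        SPAD measurement cube on the low-res grid.
    c
        CCD intensity image on the high-res grid.  Passed through
        :func:`rescale_ccd` first unless ``rescale=False`` (the rescale is
        skipped automatically when ``alpha == 0``, where ``c`` is unused).
    geometry, weights
        Measurement geometry and objective weights (see
        :data:`WEIGHT_PRESETS` for the published presets).
    solver
        ``"pdhg"`` (exact cone form, default) or ``"lbfgs"`` (smoothed).
    max_iter, tol
        Iteration cap and relative-step stopping tolerance.
    squared
        Use squared L2 data terms instead of the printed unsquared form.
    discrepancy
        Morozov stopping for photon-count data: iteration halts once the
        data residual ``||A_tau i - d||_2`` falls to this level.  The
        default ``"auto"`` uses ``sqrt(total counts in d)``, the expected
        Poisson residual at the true cube — driving the residual further
        below the noise floor overfits shot noise (semi-convergence) and
        demonstrably degrades depth and lifetime accuracy.  Pass ``None``
        to disable (e.g. for noiseless data) and solve to ``tol``.
    step_ratio
        Dual/primal step-size ratio for PDHG; by default set automatically
        from the photon-count scale of the back-projected initializer.

    Reconstruction is deterministic: no randomness enters the solver.
    """
    if d.grid != LOW:
        raise ValueError("d must be on the low-res grid")
    if d.values.shape[1:] != geometry.low_shape:
        raise ValueError(
            f"d spatial shape {d.values.shape[1:]} does not match geometry "
            f"{geometry.low_shape}"
        )
    if c.grid != HIGH or c.values.shape != geometry.high_shape:
        raise ValueError("c must be a high-res image matching the geometry")

    ccd_scale = 1.0
    c_used = c
    if rescale and weights.alpha > 0 and c.total() > 0:
        c_used = rescale_ccd(c, d, geometry)
        ccd_scale = c_used.total() / c.total() if c.total() > 0 else 1.0

    if discrepancy == "auto":
        discrepancy = float(np.sqrt(max(d.total(), 0.0)))
    elif discrepancy is not None:
        discrepancy = float(discrepancy)
        if discrepancy <= 0:
            discrepancy = None

    solvers = {"pdhg": _solve_pdhg, "lbfgs": _solve_lbfgs}
    if solver not in solvers:
        raise ValueError(f"unknown solver {solver!r}; choose from {sorted(solvers)}")
    kwargs = dict(max_iter=max_iter, tol=tol, squared=squared, discrepancy=discrepancy)
    if solver == "pdhg":
        kwargs["verbose"] = verbose
        kwargs["step_ratio"] = step_ratio
    x, status, n_iter, diag = solvers[solver](
        d.values, c_used.values, geometry, weights, **kwargs
    )

    x = np.maximum(x, 0.0)
    cube = TransientCube(x, bin_width=d.bin_width, grid=HIGH)
    obj = objective_value(cube, d, c_used, geometry, weights, squared=squared)
    diag = dict(diag, ccd_scale=ccd_scale, solver=solver)
    return ReconstructionResult(
        cube=cube, objective=obj, solver_status=status, n_iter=n_iter, diagnostics=diag
    )
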