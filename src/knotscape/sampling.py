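"""Local minimisation, basin-hopping, and radial bias protocols.

Basin-hopping perturbs the current minimum, re-minimises, and applies a
Metropolis test on the *minimised* energies, so moves need not respect
detailed balance.  Three move sets are provided:

* ``unrestricted`` — large coordinate perturbations comparable to the
  bond length; efficient but allows chain crossing, so it samples the
  topologically unconstrained landscape.
* ``small_step`` — maximum perturbation 0.69, small enough to prevent
  the chain from passing through itself, preserving the knot type.
* ``compress_release`` — each perturbation is followed by minimisation
  under an added compressive radial potential (harmonic, k around 5)
  that is switched off once the combined root-mean-squared gradient
  falls below a threshold (around 0.01); the compression deforms the
  ring into a neighbouring basin without changing the topology.

The expansion protocol ramps a negative radial force constant (k = -15,
p = 1 suffices for every minimum encountered here) to swell compact
structures so their crossings can be counted and classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .polymer_model import (
    BiasParams,
    PotentialParams,
    RingConfiguration,
    align,
    energy_and_gradient,
    hessian,
    radial_bias,
    zero_mode_threshold,
)

__all__ = [
    "MinimizerSettings",
    "BasinHoppingSettings",
    "MinimumRecord",
    "BasinHoppingResult",
    "MinimizationFailure",
    "minimize",
    "minimize_config",
    "perturb",
    "compress_release_move",
    "basin_hop",
    "expand",
]


class MinimizationFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class MinimizerSettings:
    rms_grad_tol: float = 1e-6
    max_iterations: int = 20000
    history_size: int = 30

    def __post_init__(self):
        if self.rms_grad_tol <= 0:
            raise ValueError("rms_grad_tol must be positive")


@dataclass(frozen=True)
class BasinHoppingSettings:
    """Move size, Metropolis acceptance temperature (energy units),
    step count, move set and RNG seed for one basin-hopping run."""

    max_step: float = 0.69
    temperature: float = 1.0
    n_steps: int = 500
    move_kind: str = "unrestricted"
    seed: int = 0
    compress_k: float = 5.0
    rms_switch: float = 0.01

    def __post_init__(self):
        if self.max_step <= 0 or self.temperature <= 0:
            raise ValueError("max_step and temperature must be positive")
        if self.move_kind not in ("unrestricted", "small_step", "compress_release"):
            raise ValueError(f"unknown move_kind {self.move_kind!r}")


@dataclass
class MinimumRecord:
    """A converged local minimum with its harmonic summary.

    ``log_prod_pos_eig`` is sum(ln lambda) over the kappa = 3N - 6
    positive Hessian eigenvalues; ``weight`` is the permutational
    degeneracy (2N for a ring with trivial point group).
    """

    id: int
    energy: float
    coords: np.ndarray | None
    log_prod_pos_eig: float
    weight: float
    knot_label: str | None = None


@dataclass
class BasinHoppingResult:
    minima: list[MinimumRecord]
    lowest: MinimumRecord
    accepted: int
    rejected: int
    lowest_trace: list[float] = field(default_factory=list)


# --- local minimisation -----------------------------------------------------

def _lbfgs(x0: np.ndarray, fun_grad, settings: MinimizerSettings,
           stop_rms: float | None = None) -> tuple[np.ndarray, float]:
    """L-BFGS descent to RMS gradient below the tolerance (or below
    ``stop_rms`` for the early-switch phase of compress-release)."""
    n = x0.size
    target_rms = stop_rms if stop_rms is not None else settings.rms_grad_tol

    class _Stop(Exception):
        pass

    state = {}

    def f(x):
        e, g = fun_grad(x.reshape(-1, 3))
        state["x"], state["g"] = x.copy(), g.ravel()
        return e, g.ravel()

    def cb(xk):
        if stop_rms is not None:
            _, g = fun_grad(xk.reshape(-1, 3))
            if np.sqrt((g * g).mean()) < stop_rms:
                raise _Stop

    x = x0.ravel()
    rms = np.inf
    for _restart in range(4):  # fresh curvature memory if the line search stalls
        try:
            res = _scipy_minimize(
                f, x, jac=True, method="L-BFGS-B",
                callback=cb if stop_rms is not None else None,
                options={
                    "maxiter": settings.max_iterations,
                    "maxcor": settings.history_size,
                    "gtol": target_rms,      # max-norm <= tol implies RMS <= tol
                    "ftol": 1e-16,
                    "maxfun": 10 * settings.max_iterations,
                },
            )
            x = res.x
        except _Stop:
            x = state["x"]
        _, g = fun_grad(x.reshape(-1, 3))
        rms = float(np.sqrt((g * g).mean()))
        if rms <= target_rms:
            break
    if stop_rms is None and rms > settings.rms_grad_tol:
        raise MinimizationFailure(f"did not converge: RMS gradient {rms:.3e}")
    return x.reshape(-1, 3), rms


def minimize_config(
    config: RingConfiguration,
    params: PotentialParams,
    settings: MinimizerSettings | None = None,
) -> RingConfiguration:
    """Quasi-Newton descent of the model potential; returns the relaxed
    geometry without building a record.  If the line search stalls just
    above tolerance, a few eigenvector-following Newton steps with the
    analytic Hessian finish the job."""
    settings = settings or MinimizerSettings()
    fun = lambda c: energy_and_gradient(RingConfiguration(c), params)
    try:
        coords, _ = _lbfgs(config.coords, fun, settings)
    except MinimizationFailure:
        loose = MinimizerSettings(
            rms_grad_tol=1e-4, max_iterations=settings.max_iterations,
            history_size=settings.history_size,
        )
        coords, _ = _lbfgs(config.coords, fun, loose)
        coords = _newton_polish(coords, params, settings.rms_grad_tol)
    return RingConfiguration(coords)


def _newton_polish(coords: np.ndarray, params: PotentialParams,
                   rms_tol: float, max_steps: int = 10) -> np.ndarray:
    """Eigenvector-following descent steps dx = -sum (g.v)/|lam| v with
    zero modes excluded; quadratic convergence near a stationary point."""
    for _ in range(max_steps):
        cfg = RingConfiguration(coords)
        _, g = energy_and_gradient(cfg, params)
        rms = float(np.sqrt((g * g).mean()))
        if rms <= rms_tol:
            return coords
        lam, vec = np.linalg.eigh(hessian(cfg, params))
        tol = zero_mode_threshold(lam)
        keep = np.abs(lam) >= tol
        gv = vec[:, keep].T @ g.ravel()
        step = -(vec[:, keep] @ (gv / np.abs(lam[keep])))
        norm = np.linalg.norm(step)
        if norm > 0.5:  # trust radius: polish only
            step *= 0.5 / norm
        coords = coords + step.reshape(-1, 3)
    cfg = RingConfiguration(coords)
    _, g = energy_and_gradient(cfg, params)
    rms = float(np.sqrt((g * g).mean()))
    if rms > rms_tol:
        raise MinimizationFailure(f"did not converge: RMS gradient {rms:.3e}")
    return coords


class _SaddleConvergence(MinimizationFailure):
    def __init__(self, eigenvector: np.ndarray):
        super().__init__("converged to a saddle (negative eigenvalue)")
        self.eigenvector = eigenvector


def _record_from_config(
    config: RingConfiguration, params: PotentialParams, min_id: int = -1
) -> MinimumRecord:
    from .polymer_model import rigid_body_basis

    energy, _ = energy_and_gradient(config, params)
    h = hessian(config, params)
    q = rigid_body_basis(config.coords)
    p = np.eye(h.shape[0]) - q @ q.T
    shift = 10.0 * float(np.abs(h).max()) + 1.0
    lam, vec = np.linalg.eigh(p @ h @ p + shift * (q @ q.T))
    lam, vec = lam[:-6], vec[:, :-6]
    tol = zero_mode_threshold(lam)
    if lam[0] <= -tol:
        raise _SaddleConvergence(vec[:, 0].reshape(-1, 3))
    pos = lam[lam >= tol]
    if len(pos) != 3 * config.n_beads - 6:
        raise MinimizationFailure(
            f"expected {3 * config.n_beads - 6} positive eigenvalues, got {len(pos)}"
        )
    return MinimumRecord(
        id=min_id,
        energy=float(energy),
        coords=config.coords.copy(),
        log_prod_pos_eig=float(np.log(pos).sum()),
        weight=2.0 * config.n_beads,
    )


def minimize(
    config: RingConfiguration,
    params: PotentialParams,
    settings: MinimizerSettings | None = None,
) -> MinimumRecord:
    """Minimise and return a MinimumRecord with the harmonic summary.

    Symmetric starting geometries occasionally descend onto a saddle
    with vanishing gradient; such points are escaped by a small kick
    along the negative-curvature eigenvector before re-descending.
    Raises MinimizationFailure on non-convergence or if no true minimum
    is reached after a few escape attempts."""
    relaxed = minimize_config(config, params, settings)
    for _ in range(5):
        try:
            return _record_from_config(relaxed, params)
        except _SaddleConvergence as sc:
            kicked = RingConfiguration(relaxed.coords + 0.05 * sc.eigenvector)
            relaxed = minimize_config(kicked, params, settings)
    raise MinimizationFailure("could not escape saddle convergence")


# --- basin-hopping ----------------------------------------------------------

def perturb(
    config: RingConfiguration, max_step: float, rng: np.random.Generator
) -> RingConfiguration:
    """Independent uniform displacement in [-max_step, +max_step] for
    every Cartesian coordinate."""
    if max_step < 0:
        raise ValueError("max_step must be non-negative")
    disp = rng.uniform(-max_step, max_step, size=config.coords.shape)
    return RingConfiguration(config.coords + disp)


def compress_release_move(
    config: RingConfiguration,
    params: PotentialParams,
    k_bias: float = 5.0,
    power: int = 2,
    rms_switch: float = 0.01,
    settings: MinimizerSettings | None = None,
) -> MinimumRecord:
    """Minimise under model + compressive radial bias until the combined
    RMS gradient drops below ``rms_switch``, then finish minimising the
    unbiased model.  The compression phase cannot push the chain
    through itself, so the knot type of the output equals the input's.
    """
    if k_bias < 0:
        raise ValueError("compressive k_bias must be >= 0")
    settings = settings or MinimizerSettings()
    work = config
    if k_bias > 0:
        bias = BiasParams(k_bias=k_bias, power=power)

        def combined(c):
            cfg = RingConfiguration(c)
            e, g = energy_and_gradient(cfg, params)
            eb, gb = radial_bias(cfg, bias)
            return e + eb, g + gb

        coords, _ = _lbfgs(work.coords, combined, settings, stop_rms=rms_switch)
        work = RingConfiguration(coords)
    return minimize(work, params, settings)


def basin_hop(
    start_config: RingConfiguration,
    params: PotentialParams,
    bh: BasinHoppingSettings,
    settings: MinimizerSettings | None = None,
) -> BasinHoppingResult:
    """Basin-hopping with Metropolis acceptance on minimised energies.

    Minima are deduplicated by energy window (1e-6) plus permutational
    alignment distance (< 1e-3); the running lowest minimum is traced.
    """
    settings = settings or MinimizerSettings()
    rng = np.random.default_rng(bh.seed)
    current = minimize(start_config, params, settings)
    minima: list[MinimumRecord] = [current]
    current.id = 0
    lowest = current
    accepted = rejected = 0
    trace = [lowest.energy]
    for _ in range(bh.n_steps):
        trial_cfg = perturb(RingConfiguration(current.coords), bh.max_step, rng)
        try:
            if bh.move_kind == "compress_release":
                trial = compress_release_move(
                    trial_cfg, params, k_bias=bh.compress_k,
                    rms_switch=bh.rms_switch, settings=settings,
                )
            else:
                trial = minimize(trial_cfg, params, settings)
        except MinimizationFailure:
            rejected += 1
            trace.append(lowest.energy)
            continue
        de = trial.energy - current.energy
        if de <= 0 or rng.random() < np.exp(-de / bh.temperature):
            accepted += 1
            stored = _store_minimum(minima, trial)
            current = stored
            if stored.energy < lowest.energy:
                lowest = stored
        else:
            rejected += 1
        trace.append(lowest.energy)
    return BasinHoppingResult(
        minima=minima, lowest=lowest, accepted=accepted, rejected=rejected,
        lowest_trace=trace,
    )


def _store_minimum(
    minima: list[MinimumRecord],
    candidate: MinimumRecord,
    energy_tol: float = 1e-6,
    dist_tol: float = 1e-3,
) -> MinimumRecord:
    """Deduplicate against the stored set; permutational copies merge
    onto the first-found representative."""
    for m in minima:
        if abs(m.energy - candidate.energy) < energy_tol:
            d = align(
                RingConfiguration(m.coords), RingConfiguration(candidate.coords)
            ).distance
            if d < dist_tol:
                return m
    candidate.id = len(minima)
    minima.append(candidate)
    return candidate


# --- radial expansion -------------------------------------------------------

def expand(
    config: RingConfiguration,
    params: PotentialParams,
    k_target: float = -15.0,
    power: int = 1,
    n_stages: int = 10,
    settings: MinimizerSettings | None = None,
    return_frames: bool = False,
):
    """Swell a compact ring by ramping a negative radial force constant.

    The bias is ramped from 0 to ``k_target`` in ``n_stages`` equal
    steps, minimising the combined potential at each stage; barriers to
    chain crossing dwarf anything met during expansion, so the knot
    type is conserved while the radius of gyration grows.  Returns the
    expanded configuration (and the per-stage frames if requested); a
    failed stage returns the last good stage with ``warning`` set.
    """
    if k_target >= 0:
        raise ValueError("k_target must be negative (expansion)")
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    settings = settings or MinimizerSettings(rms_grad_tol=1e-5)
    frames = [config.copy()]
    work = config
    warning = False
    for stage in range(1, n_stages + 1):
        bias = BiasParams(k_bias=k_target * stage / n_stages, power=power)

        def combined(c):
            cfg = RingConfiguration(c)
            e, g = energy_and_gradient(cfg, params)
            eb, gb = radial_bias(cfg, bias)
            return e + eb, g + gb

        try:
            coords, _ = _lbfgs(work.coords, combined, settings)
        except MinimizationFailure:
            warning = True
            break
        work = RingConfiguration(coords)
        frames.append(work.copy())
    if return_frames:
        return work, frames, warning
    return work
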