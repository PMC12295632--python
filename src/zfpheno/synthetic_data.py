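"""Seeded generators for synthetic swim cohorts and LFQ matrices.

Swim trajectories follow a two-state alternating-renewal model of larval
locomotion: quiescent periods end at exponentially distributed times whose
hazard (the bolt-initiation rate) depends on the current light condition,
and bolts last gamma-distributed durations during which the larva swims at
truncated-normal speeds with a random-walk heading inside a reflecting
circular well (24-well plate scale, 10 mm diameter). Light onsets act as
an instantaneous multiplier on the initiation rate — the minimal mechanism
for a light-evoked activity peak. The control defaults triple the
initiation rate in light; the hypokinetic ("MPP+-like") defaults use a
low, light-insensitive rate, reproducing the reduced-distance,
fewer-bolts, longer-pauses, no-light-response phenotype while leaving
within-bolt speed and duration untouched (movement quality is preserved;
initiation is impaired).

LFQ matrices are log-normal: protein base abundances are normal on the
log2 scale, a chosen subset carries a group effect of fixed magnitude and
random sign, replicate noise is additive on the log2 scale, and
missingness is Bernoulli per cell with an optional low-abundance boost
(missing-not-at-random), which is what makes the replicate-consistency
filter do real work.

Everything is deterministic given the seed; per-larva and per-matrix
streams are derived from the master seed by a counter-based spawn so
results do not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .trajectory_io import CohortDataset, LightSchedule, Trajectory, standard_schedule

__all__ = [
    "WELL_RADIUS_MM",
    "SwimParams",
    "LFQSimParams",
    "control_swim_params",
    "hypokinetic_swim_params",
    "simulate_larva",
    "simulate_cohort",
    "simulate_lfq",
]

#: Reflecting circular boundary radius (10 mm well diameter).
WELL_RADIUS_MM = 5.0


@dataclass(frozen=True)
class SwimParams:
    """Parameters of the alternating-renewal swim model (rates in events/s,
    speeds in mm/s, durations in s, angles in rad)."""

    bolt_rate_dark: float = 0.25
    bolt_rate_light: float = 0.75
    bolt_duration_mean_s: float = 0.6
    bolt_duration_shape: float = 2.0
    within_bolt_speed_mean_mms: float = 6.0
    within_bolt_speed_sd_mms: float = 2.0
    quiescent_jitter_mms: float = 0.02
    turn_sd_rad: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bolt_rate_dark",
            "bolt_rate_light",
            "bolt_duration_mean_s",
            "bolt_duration_shape",
            "within_bolt_speed_mean_mms",
            "within_bolt_speed_sd_mms",
            "quiescent_jitter_mms",
            "turn_sd_rad",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def control_swim_params(seed: int = 0) -> SwimParams:
    """Control phenotype: light triples the bolt-initiation rate."""
    return SwimParams(seed=seed)


def hypokinetic_swim_params(seed: int = 0) -> SwimParams:
    """Hypokinetic phenotype: rare bolts, no light modulation; within-bolt
    speed and duration match the control (initiation, not execution, is hit)."""
    return SwimParams(bolt_rate_dark=0.05, bolt_rate_light=0.05, seed=seed)


@dataclass(frozen=True)
class LFQSimParams:
    """Parameters of the log-normal LFQ generator (log2 scale throughout)."""

    n_proteins: int = 2000
    n_de: int = 100
    effect_log2fc: float = 2.0  # magnitude; sign drawn at random per protein
    base_log2_mean: float = 23.0
    base_log2_sd: float = 2.0
    replicate_noise_sd: float = 0.25
    n_replicates: int = 2
    missing_rate: float = 0.05
    low_abundance_missing_boost: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_de <= self.n_proteins:
            raise ValidationError("need 0 <= n_de <= n_proteins")
        if self.n_replicates < 2:
            raise ValidationError("need at least 2 replicates per group")
        if not (0 <= self.missing_rate <= 1 and 0 <= self.low_abundance_missing_boost <= 1):
            raise ValidationError("missingness probabilities must lie in [0, 1]")


def _child_seed(master: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master), spawn_key=(int(index),))


def _bolt_windows(
    rng: np.random.Generator, p: SwimParams, schedule: LightSchedule, t_end: float
) -> list[tuple[float, float]]:
    """Continuous-time bolt [start, end) windows of the alternating-renewal
    process on [0, t_end], rate switching with the light condition."""
    rate = {"light": p.bolt_rate_light, "dark": p.bolt_rate_dark}
    epochs = list(schedule.epochs)
    windows: list[tuple[float, float]] = []
    t = 0.0
    while t < t_end:
        # Quiescence: piecewise-exponential waiting time via a unit-rate
        # hazard budget integrated across epochs (memoryless across switches).
        budget = rng.exponential(1.0)
        start = None
        tq = t
        for es, ee, cond in epochs:
            if ee <= tq:
                continue
            seg_start = max(tq, es)
            r = rate[cond]
            if r <= 0:
                continue
            need = budget / r
            if seg_start + need <= ee:
                start = seg_start + need
                break
            budget -= r * (ee - seg_start)
        if start is None or start >= t_end:
            break
        dur = rng.gamma(p.bolt_duration_shape, p.bolt_duration_mean_s / p.bolt_duration_shape)
        end = min(start + dur, t_end)
        windows.append((start, end))
        t = end
    return windows


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 by resampling (fast here: mean >> 0)."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def simulate_larva(
    p: SwimParams,
    schedule: LightSchedule | None = None,
    rate_hz: float = 25.0,
    group_label: str = "control",
    well_id: str = "w0",
) -> Trajectory:
    """One larva's trajectory sampled on a uniform grid spanning the schedule.

    Per sampling step the speed is a fresh truncated-normal draw inside a
    bolt window (by step midpoint) and the constant sub-threshold jitter
    otherwise; the heading performs a Gaussian random walk; positions are
    reflected radially at the well boundary.
    """
    if rate_hz <= 0:
        raise ValidationError("rate_hz must be positive")
    if schedule is None:
        schedule = standard_schedule()
    rng = np.random.default_rng(_child_seed(p.seed, 0))
    t_end = schedule.span_s
    dt = 1.0 / rate_hz
    n_steps = int(round(t_end * rate_hz))
    t = np.arange(n_steps + 1) * dt
    windows = _bolt_windows(rng, p, schedule, t_end)
    mid = t[:-1] + dt / 2.0
    in_bolt = np.zeros(n_steps, dtype=bool)
    for s, e in windows:
        in_bolt |= (mid >= s) & (mid < e)
    speeds = np.full(n_steps, p.quiescent_jitter_mms)
    nb = int(in_bolt.sum())
    if nb:
        speeds[in_bolt] = _truncated_normal(
            rng, p.within_bolt_speed_mean_mms, p.within_bolt_speed_sd_mms, nb
        )
    # Heading: random walk during bolts, fresh isotropic draw per quiescent
    # step (jitter has no persistent direction).
    turns = rng.normal(0.0, p.turn_sd_rad, n_steps)
    iso = rng.uniform(-np.pi, np.pi, n_steps)
    heading = np.empty(n_steps)
    h = rng.uniform(-np.pi, np.pi)
    for i in range(n_steps):
        if in_bolt[i]:
            h = h + turns[i]
            heading[i] = h
        else:
            heading[i] = iso[i]
            h = iso[i]
    dx = speeds * dt * np.cos(heading)
    dy = speeds * dt * np.sin(heading)
    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    x[0] = y[0] = 0.0
    px = py = 0.0
    R = WELL_RADIUS_MM
    for i in range(n_steps):
        px += dx[i]
        py += dy[i]
        r = np.hypot(px, py)
        if r > R:
            # Radial reflection: fold the overshoot back inside.
            scale = (2.0 * R - r) / r
            px *= scale
            py *= scale
        x[i + 1] = px
        y[i + 1] = py
    return Trajectory(well_id=well_id, group=group_label, rate_hz=rate_hz, t=t, x=x, y=y)


def simulate_cohort(
    control: SwimParams | None = None,
    treated: SwimParams | None = None,
    n_per_group: int = 12,
    schedule: LightSchedule | None = None,
    rate_hz: float = 25.0,
    seed: int = 0,
) -> CohortDataset:
    """A two-group cohort (default 12 larvae/group) with per-larva derived seeds."""
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if schedule is None:
        schedule = standard_schedule()
    control = control if control is not None else control_swim_params()
    treated = treated if treated is not None else hypokinetic_swim_params()
    larvae = []
    for idx in range(n_per_group * 2):
        group = "control" if idx < n_per_group else "treated"
        params = control if group == "control" else treated
        child = int(_child_seed(seed, idx + 1).generate_state(1)[0] % 2**31)
        well = f"{'C' if group == 'control' else 'T'}{(idx % n_per_group) + 1:02d}"
        larvae.append(
            simulate_larva(
                replace(params, seed=child), schedule, rate_hz, group_label=group, well_id=well
            )
        )
    metadata = {
        "n_per_group": n_per_group,
        "rate_hz": rate_hz,
        "seed": seed,
        "control_params": control.__dict__ | {"seed": None},
        "treated_params": treated.__dict__ | {"seed": None},
    }
    return CohortDataset(larvae=larvae, schedule=schedule, metadata=metadata)


def simulate_lfq(p: LFQSimParams):
    """Synthetic LFQ matrix plus its ground truth.

    Returns ``(LFQMatrix, truth)`` where truth is a DataFrame with columns
    protein_id, gene_symbol, true_log2fc (exactly n_de nonzero entries).
    The matrix is on the raw intensity scale with NaN for missing cells.
    """
    import pandas as pd

    from .proteomics_de import LFQMatrix

    rng = np.random.default_rng(_child_seed(p.seed, 0))
    n, r = p.n_proteins, p.n_replicates
    protein_ids = [f"P{i + 1:05d}" for i in range(n)]
    gene_symbols = [f"G{i + 1:05d}" for i in range(n)]
    base = rng.normal(p.base_log2_mean, p.base_log2_sd, n)
    true_fc = np.zeros(n)
    de_idx = rng.choice(n, size=p.n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=p.n_de)
    true_fc[de_idx] = signs * p.effect_log2fc
    log2_ctrl = base[:, None] + rng.normal(0.0, p.replicate_noise_sd, (n, r))
    log2_trt = (base + true_fc)[:, None] + rng.normal(0.0, p.replicate_noise_sd, (n, r))
    log2_all = np.concatenate([log2_ctrl, log2_trt], axis=1)
    intensities = np.exp2(log2_all)
    # Missingness: baseline rate plus a logistic low-abundance boost keyed to
    # the protein's base level one SD below the mean.
    if p.missing_rate > 0 or p.low_abundance_missing_boost > 0:
        knee = p.base_log2_mean - p.base_log2_sd
        width = max(p.base_log2_sd / 2.0, 1e-9)
        p_miss = p.missing_rate + p.low_abundance_missing_boost / (
            1.0 + np.exp((base - knee) / width)
        )
        p_miss = np.clip(p_miss, 0.0, 1.0)
        drop = rng.uniform(size=intensities.shape) < p_miss[:, None]
        intensities = np.where(drop, np.nan, intensities)
    cols = [f"ctrl_{i + 1}" for i in range(r)] + [f"trt_{i + 1}" for i in range(r)]
    samples = pd.DataFrame(
        {
            "group": ["control"] * r + ["treated"] * r,
            "replicate": list(range(1, r + 1)) * 2,
        },
        index=pd.Index(cols, name="sample"),
    )
    matrix = LFQMatrix(
        intensities=pd.DataFrame(intensities, index=pd.Index(protein_ids, name="protein_id"), columns=cols),
        samples=samples,
        gene_symbols=pd.Series(gene_symbols, index=protein_ids, name="gene_symbol"),
    )
    truth = pd.DataFrame(
        {"protein_id": protein_ids, "gene_symbol": gene_symbols, "true_log2fc": true_fc}
    )
    return matrix, truth
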