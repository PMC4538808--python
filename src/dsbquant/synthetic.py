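"""Stochastic generators for qPCR-resection, ChIP, blot, and foci datasets.

Each generator emits the same long-format tables the analysis modules read, so
every downstream stage can be exercised end to end without any external data.
Closed-form expectations (`expected_unresected_fraction`,
`chip_expected_enrichment`, `blot_expected_level`) accompany the stochastic
generators and act as their analytic oracles.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .config import (
    AmpliconPanel,
    BlotSimConfig,
    ChipSimConfig,
    FociSimConfig,
    ResectionSimConfig,
)

__all__ = [
    "simulate_resection_qpcr",
    "expected_unresected_fraction",
    "simulate_chip_profile",
    "chip_expected_enrichment",
    "simulate_blot",
    "blot_expected_level",
    "simulate_foci",
]


def _check_timepoints(timepoints_h: Sequence[float], require_zero: bool = True) -> np.ndarray:
    t = np.asarray(list(timepoints_h), dtype=float)
    if t.size == 0:
        raise ValueError("timepoints_h is empty")
    if np.any(t < 0):
        raise ValueError("timepoints must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if require_zero and t[0] != 0.0:
        raise ValueError("timepoints must include t=0")
    return t


def _draw_cells(config: ResectionSimConfig, rng: np.random.Generator):
    """Draw per-cell cut status, cut time and front speed."""
    n = config.n_cells
    cut = rng.random(n) < config.cut_fraction
    if math.isinf(config.cut_rate):
        cut_time = np.zeros(n)
    else:
        cut_time = rng.exponential(1.0 / config.cut_rate, size=n)
    if config.speed_cv == 0:
        speed = np.full(n, config.speed_mean_kb_h)
    else:
        shape = 1.0 / config.speed_cv**2
        scale = config.speed_mean_kb_h * config.speed_cv**2
        speed = rng.gamma(shape, scale, size=n)
    return cut, cut_time, speed


def unresected_fractions(
    config: ResectionSimConfig,
    distances_kb: Sequence[float],
    timepoints_h: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise-free Monte-Carlo unresected fraction, shape (n_times, n_distances).

    A cell's amplicon at distance d is lost once the resection front has
    travelled at least d kb, i.e. V*(t - T - delay) >= d. Sampling the same
    simulated cells at every timepoint mirrors repeated sampling of one
    culture.
    """
    d = np.asarray(distances_kb, dtype=float)
    t = np.asarray(timepoints_h, dtype=float)
    cut, cut_time, speed = _draw_cells(config, rng)
    # front position per cell per time; uncut cells never lose signal
    frac = np.empty((t.size, d.size))
    for i, ti in enumerate(t):
        front = speed * (ti - cut_time - config.init_delay_h)
        front[~cut] = -np.inf
        front.sort()
        # unresected at d <=> front < d
        frac[i] = np.searchsorted(front, d, side="left") / config.n_cells
    return frac


def simulate_resection_qpcr(
    config: ResectionSimConfig,
    panel: AmpliconPanel,
    timepoints_h: Sequence[float],
    *,
    condition: str = "simulated",
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate a long-format qPCR resection table.

    Per replicate an independent culture of ``config.n_cells`` cells is drawn;
    the emitted quantity for a non-control amplicon is the unresected fraction
    across cells times multiplicative lognormal noise, and the control-locus
    quantity is 1 times noise.

    Returns a DataFrame with columns
    ``condition, replicate, time_h, amplicon, quantity``.
    """
    t = _check_timepoints(timepoints_h)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = np.random.SeedSequence(config.seed).spawn(n_replicates)
    target_distances = [a.distance_kb for a in panel.targets]
    target_names = [a.name for a in panel.targets]
    control_names = [a.name for a in panel.controls]

    rows = []
    for rep, ss in enumerate(seeds, start=1):
        rng = np.random.default_rng(ss)
        frac = unresected_fractions(config, target_distances, t, rng)
        n_noise = (len(target_names) + len(control_names)) * t.size
        if config.noise_sigma > 0:
            noise = rng.lognormal(0.0, config.noise_sigma, size=n_noise)
        else:
            noise = np.ones(n_noise)
        k = 0
        for i, ti in enumerate(t):
            for j, name in enumerate(target_names):
                rows.append((condition, rep, ti, name, frac[i, j] * noise[k]))
                k += 1
            for name in control_names:
                rows.append((condition, rep, ti, name, 1.0 * noise[k]))
                k += 1
    return pd.DataFrame(rows, columns=["condition", "replicate", "time_h", "amplicon", "quantity"])


def expected_unresected_fraction(
    config: ResectionSimConfig, distance_kb: float, time_h: float
) -> float:
    """Analytic unresected fraction 1 - p_cut * P(T + delay + d/V <= t).

    Closed form for a deterministic speed (cv=0); numerical integration over
    the Gamma speed density otherwise. Noise-free and deterministic.
    """
    if distance_kb <= 0:
        raise ValueError("distance_kb must be > 0")
    if time_h < 0:
        raise ValueError("time_h must be >= 0")
    d, t = distance_kb, time_h
    avail = t - config.init_delay_h
    if avail <= 0:
        return 1.0
    kappa, p = config.cut_rate, config.cut_fraction
    if config.speed_cv == 0:
        x = avail - d / config.speed_mean_kb_h
        if x <= 0:
            return 1.0
        p_cut_and_passed = 1.0 if math.isinf(kappa) else 1.0 - math.exp(-kappa * x)
        return 1.0 - p * p_cut_and_passed

    shape = 1.0 / config.speed_cv**2
    scale = config.speed_mean_kb_h * config.speed_cv**2
    v_min = d / avail  # slower cells cannot have passed d even if cut at t=0

    if math.isinf(kappa):
        return 1.0 - p * stats.gamma.sf(v_min, shape, scale=scale)

    def integrand(v: float) -> float:
        x = avail - d / v
        return stats.gamma.pdf(v, shape, scale=scale) * (1.0 - math.exp(-kappa * x))

    prob, _ = integrate.quad(integrand, v_min, np.inf, limit=200)
    return 1.0 - p * prob


def chip_expected_enrichment(config: ChipSimConfig, position_kb: float, time_h: float) -> float:
    """Noise-free fold-enrichment E(x, t) of the ChIP model.

    Establishment: E = 1 + (emax-1)*(1-exp(-t/tau_on)) within the spreading
    half-width. After repair (repairable locus) the excess enrichment relaxes
    toward 1 with tau_off; after checkpoint-kinase inhibition (caffeine) the
    establishment term is frozen at its value at treatment time and decays by
    decay_factor per hour.
    """
    if time_h < 0:
        raise ValueError("time_h must be >= 0")
    if abs(position_kb) > config.spread_kb:
        return 1.0
    t = time_h
    amp = config.emax_fold - 1.0

    def establishment(u: float) -> float:
        return 1.0 - math.exp(-u / config.tau_on_h)

    if config.caffeine_time_h is not None and t > config.caffeine_time_h:
        frozen = amp * establishment(config.caffeine_time_h)
        return 1.0 + frozen * config.decay_factor_per_h ** (t - config.caffeine_time_h)
    if config.repair_time_h is not None and t > config.repair_time_h:
        at_repair = amp * establishment(config.repair_time_h)
        return 1.0 + at_repair * math.exp(-(t - config.repair_time_h) / config.tau_off_h)
    return 1.0 + amp * establishment(t)


def simulate_chip_profile(
    config: ChipSimConfig,
    positions_kb: Sequence[float],
    timepoints_h: Sequence[float],
    *,
    locus: str = "DSB",
    n_replicates: int = 1,
    base_ip_over_input: float = 0.05,
) -> pd.DataFrame:
    """Simulate a locus-directed ChIP-qPCR table (IP and input quantities).

    Positions may be signed (either side of the break). A control locus with
    enrichment 1 at all times is appended so the analysis stage can
    reconstruct fold-enrichment by the double ratio. Returns a DataFrame with
    columns ``locus, position_kb, time_h, replicate, ip, input, is_control``.
    """
    t = _check_timepoints(timepoints_h)
    pos = np.asarray(list(positions_kb), dtype=float)
    if pos.size == 0:
        raise ValueError("positions_kb is empty")
    seeds = np.random.SeedSequence(config.seed).spawn(n_replicates)
    rows = []
    for rep, ss in enumerate(seeds, start=1):
        rng = np.random.default_rng(ss)

        def noisy() -> float:
            if config.noise_sigma > 0:
                return float(rng.lognormal(0.0, config.noise_sigma))
            return 1.0

        for ti in t:
            for x in pos:
                e = chip_expected_enrichment(config, float(x), float(ti))
                inp = 1.0 * noisy()
                ip = base_ip_over_input * e * noisy()
                rows.append((locus, float(x), float(ti), rep, ip, inp, False))
            rows.append(
                ("control_locus", 0.0, float(ti), rep, base_ip_over_input * noisy(), 1.0 * noisy(), True)
            )
    return pd.DataFrame(
        rows, columns=["locus", "position_kb", "time_h", "replicate", "ip", "input", "is_control"]
    )


def blot_expected_level(
    config: BlotSimConfig, time_h: float, *, treated: bool, ref_time_h: float
) -> float:
    """Noise-free normalized protein level (relative to baseline) at time_h."""
    rise = (config.induction_fold - 1.0) * min(time_h, ref_time_h) / ref_time_h
    untreated = config.baseline * (1.0 + rise)
    if not treated or time_h <= config.treat_time_h:
        return untreated
    at_treat = config.baseline * (
        1.0 + (config.induction_fold - 1.0) * min(config.treat_time_h, ref_time_h) / ref_time_h
    )
    return at_treat * 2.0 ** (-(time_h - config.treat_time_h) / config.half_life_h)


def simulate_blot(
    config: BlotSimConfig,
    timepoints_h: Sequence[float],
    *,
    conditions: Sequence[str] = ("untreated", "treated"),
) -> pd.DataFrame:
    """Simulate densitometry lane series for untreated and treated cultures.

    Returns a DataFrame with columns ``condition, time_h, band, loading``.
    Lane intensity = level x loading_level x exposure x noise; the loading
    control gets its own noise draw.
    """
    t = _check_timepoints(timepoints_h, require_zero=False)
    if not t[0] <= config.treat_time_h <= t[-1]:
        raise ValueError(
            f"treat_time_h={config.treat_time_h} outside simulated range [{t[0]}, {t[-1]}]"
        )
    ref = config.ref_time_h if config.ref_time_h is not None else float(t[-1])
    if ref <= 0:
        raise ValueError("reference time for induction must be > 0")
    rng = np.random.default_rng(config.seed)

    def noisy() -> float:
        return float(rng.lognormal(0.0, config.noise_sigma)) if config.noise_sigma > 0 else 1.0

    rows = []
    for cond in conditions:
        treated = cond == "treated"
        for ti in t:
            level = blot_expected_level(config, float(ti), treated=treated, ref_time_h=ref)
            band = level * config.loading_level * config.exposure * noisy()
            loading = config.loading_level * config.exposure * noisy()
            rows.append((cond, float(ti), band, loading))
    return pd.DataFrame(rows, columns=["condition", "time_h", "band", "loading"])


def simulate_foci(
    config: FociSimConfig,
    *,
    condition: str = "simulated",
    channel: str = "RPA",
) -> pd.DataFrame:
    """Simulate per-nucleus focus counts for one condition.

    Counts are negative-binomial with mean ``mean_foci / fold_suppression``
    and size ``dispersion`` (Poisson in the infinite-dispersion limit);
    ``n_nuclei`` nuclei per experiment over ``n_experiments`` independent
    repeats. Returns a DataFrame with columns
    ``condition, experiment, nucleus, channel, count``.
    """
    rng = np.random.default_rng(config.seed)
    mean = config.effective_mean
    n = config.n_nuclei * config.n_experiments
    if math.isinf(config.dispersion):
        counts = rng.poisson(mean, size=n)
    else:
        r = config.dispersion
        counts = rng.negative_binomial(r, r / (r + mean), size=n)
    experiments = np.repeat(np.arange(1, config.n_experiments + 1), config.n_nuclei)
    nuclei = np.tile(np.arange(1, config.n_nuclei + 1), config.n_experiments)
    return pd.DataFrame(
        {
            "condition": condition,
            "experiment": experiments,
            "nucleus": nuclei,
            "channel": channel,
            "count": counts,
        }
    )
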