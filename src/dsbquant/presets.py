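"""Named, frozen generator presets matching the study conditions.

Resection presets carry the population front speeds measured for each
condition (wild type, caffeine doses, checkpoint-kinase deletions); ChIP,
blot and foci presets are calibrated so the generated data reproduce the
reported fold-changes exactly in the noise-free limit. Half-lives of the
blot presets are solved in closed form from those fold constraints.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .config import BlotSimConfig, ChipSimConfig, FociSimConfig, ResectionSimConfig

__all__ = ["get_preset", "preset_names", "PRESETS"]

_RESECTION_COMMON = dict(
    cut_rate=3.0,
    cut_fraction=0.95,
    init_delay_h=0.0,
    speed_cv=0.0,
    noise_sigma=0.05,
    n_cells=10_000,
)

# Sae2 calibration: induction doubles the untreated level by 4 h; caffeine at
# 0.5 h must leave level(4 h) = t0/3, hence untreated/treated = 6 at 4 h.
# level(4) = level(0.5) * 2^(-3.5/t_half) with level(0.5) = 1.125
#   => t_half = 3.5 / log2(3 * 1.125)
_SAE2_HALF_LIFE = 3.5 / math.log2(3.0 * 1.125)
# Dna2 calibration: untreated/treated = 5 at 4 h => treated(4) = 2/5
#   => t_half = 3.5 / log2(1.125 / 0.4)
_DNA2_HALF_LIFE = 3.5 / math.log2(1.125 / 0.4)

PRESETS: dict[str, ResectionSimConfig | ChipSimConfig | BlotSimConfig | FociSimConfig] = {
    # --- qPCR resection assay: population front speeds (kb/h) ---
    "wt_untreated": ResectionSimConfig(speed_mean_kb_h=4.2, **_RESECTION_COMMON),
    "caffeine_50mM": ResectionSimConfig(speed_mean_kb_h=2.4, **_RESECTION_COMMON),
    "caffeine_10_20mM": ResectionSimConfig(speed_mean_kb_h=2.7, **_RESECTION_COMMON),
    "mec1_tel1": ResectionSimConfig(speed_mean_kb_h=5.8, **_RESECTION_COMMON),
    "mec1_tel1_caffeine_50mM": ResectionSimConfig(speed_mean_kb_h=2.7, **_RESECTION_COMMON),
    # --- gamma-H2AX ChIP around a single HO-induced DSB ---
    "irreparable_untreated": ChipSimConfig(emax_fold=40.0, tau_on_h=1.0, spread_kb=30.0),
    "irreparable_caffeine_2h": ChipSimConfig(
        emax_fold=40.0,
        tau_on_h=1.0,
        spread_kb=30.0,
        caffeine_time_h=2.0,
        decay_factor_per_h=0.99,
    ),
    "repairable": ChipSimConfig(
        emax_fold=40.0, tau_on_h=1.0, spread_kb=30.0, repair_time_h=2.0, tau_off_h=0.5
    ),
    # --- western-blot time courses (caffeine at 0.5 h post-induction) ---
    "sae2_caffeine": BlotSimConfig(
        induction_fold=2.0, treat_time_h=0.5, half_life_h=_SAE2_HALF_LIFE, ref_time_h=4.0
    ),
    "dna2_caffeine": BlotSimConfig(
        induction_fold=2.0, treat_time_h=0.5, half_life_h=_DNA2_HALF_LIFE, ref_time_h=4.0
    ),
    # cycloheximide chase in cycling, undamaged cells: no induction, rapid loss
    "sae2_chx_cycling": BlotSimConfig(
        induction_fold=1.0, treat_time_h=0.0, half_life_h=0.25
    ),
    # --- irradiation focus counts (75 nuclei x 3 experiments) ---
    "rpa_ir": FociSimConfig(mean_foci=20.0, dispersion=5.0),
    "rpa_ir_caffeine10": FociSimConfig(mean_foci=20.0, dispersion=5.0, fold_suppression=7.0),
    "rad51_ir": FociSimConfig(mean_foci=15.0, dispersion=5.0),
    "rad51_ir_caffeine10": FociSimConfig(mean_foci=15.0, dispersion=5.0, fold_suppression=3.0),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str, *, seed: int | None = None):
    """Return a copy of the named preset, optionally with the seed replaced.

    Raises ``KeyError`` listing the available names for an unknown preset.
    """
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(preset_names())}"
        ) from None
    return replace(cfg, seed=seed) if seed is not None else replace(cfg)
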