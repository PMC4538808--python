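"""Configuration dataclasses for the synthetic-data generators and the amplicon panel.

All generator configs are frozen: presets are immutable registry entries and a
modified copy is obtained with :func:`dataclasses.replace` (typically to change
the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "Amplicon",
    "AmpliconPanel",
    "ResectionSimConfig",
    "ChipSimConfig",
    "BlotSimConfig",
    "FociSimConfig",
]


@dataclass(frozen=True)
class Amplicon:
    """A qPCR amplicon at a signed distance (kb) from the DSB.

    Control amplicons sit at an uninvolved locus; their distance is ignored.
    """

    name: str
    distance_kb: float
    is_control: bool = False


@dataclass(frozen=True)
class AmpliconPanel:
    """The set of amplicons interrogated by the resection qPCR assay.

    Requires at least one control amplicon and at least two non-control
    amplicons at distinct, strictly positive distances (resection is modelled
    on one side of the break only).
    """

    entries: tuple[Amplicon, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("amplicon names must be unique")
        if not any(a.is_control for a in self.entries):
            raise ValueError("panel needs at least one control amplicon")
        targets = self.targets
        if len({a.distance_kb for a in targets}) < 2:
            raise ValueError("panel needs >=2 non-control amplicons at distinct distances")
        for a in targets:
            if a.distance_kb <= 0:
                raise ValueError(
                    f"non-control amplicon {a.name!r} must have distance_kb > 0 "
                    "(single-sided resection)"
                )

    @property
    def targets(self) -> tuple[Amplicon, ...]:
        return tuple(a for a in self.entries if not a.is_control)

    @property
    def controls(self) -> tuple[Amplicon, ...]:
        return tuple(a for a in self.entries if a.is_control)

    @property
    def distances_kb(self) -> tuple[float, ...]:
        """Target distances sorted ascending (away from the break)."""
        return tuple(sorted(a.distance_kb for a in self.targets))

    def distance_of(self, name: str) -> float:
        for a in self.entries:
            if a.name == name:
                return a.distance_kb
        raise KeyError(f"unknown amplicon {name!r}")

    @classmethod
    def from_entries(
        cls, entries: Sequence[tuple[str, float, bool]] | Sequence[Amplicon]
    ) -> "AmpliconPanel":
        amps = tuple(a if isinstance(a, Amplicon) else Amplicon(*a) for a in entries)
        return cls(amps)

    @classmethod
    def from_csv(cls, path) -> "AmpliconPanel":
        """Read a panel CSV with columns ``amplicon,distance_kb,is_control``."""
        df = pd.read_csv(path, comment="#")
        required = {"amplicon", "distance_kb", "is_control"}
        if not required.issubset(df.columns):
            raise ValueError(f"panel CSV must have columns {sorted(required)}")
        return cls.from_entries(
            [
                Amplicon(str(r.amplicon), float(r.distance_kb), bool(r.is_control))
                for r in df.itertuples()
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "amplicon": [a.name for a in self.entries],
                "distance_kb": [a.distance_kb for a in self.entries],
                "is_control": [a.is_control for a in self.entries],
            }
        )


@dataclass(frozen=True)
class ResectionSimConfig:
    """Generative parameters of the per-cell cut/resection model.

    The population model: each cell is cut with probability ``cut_fraction``;
    cut cells draw a cut time T ~ Exponential(``cut_rate``) (``math.inf``
    means instantaneous cutting at t=0) and a 5'->3' front speed V from a
    Gamma distribution with mean ``speed_mean_kb_h`` and coefficient of
    variation ``speed_cv`` (a point mass when cv=0). The front starts
    ``init_delay_h`` after cutting and advances at V kb/h indefinitely
    (nocodazole-arrested cells: no division, no cell-cycle dynamics).
    Measurement noise is multiplicative lognormal with sigma ``noise_sigma``.
    """

    cut_rate: float = 3.0
    cut_fraction: float = 0.95
    init_delay_h: float = 0.0
    speed_mean_kb_h: float = 4.2
    speed_cv: float = 0.0
    noise_sigma: float = 0.05
    n_cells: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cut_fraction <= 1.0:
            raise ValueError("cut_fraction must be in (0, 1]")
        if self.cut_rate <= 0:
            raise ValueError("cut_rate must be > 0 (math.inf = instantaneous)")
        if self.speed_mean_kb_h <= 0:
            raise ValueError("speed_mean_kb_h must be > 0")
        if self.speed_cv < 0:
            raise ValueError("speed_cv must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.init_delay_h < 0:
            raise ValueError("init_delay_h must be >= 0")


@dataclass(frozen=True)
class ChipSimConfig:
    """Generative parameters for a gamma-H2AX ChIP time course around one DSB.

    Fold-enrichment establishes as 1 + (emax_fold-1)*(1-exp(-t/tau_on))
    within ``spread_kb`` of the break. If ``repair_time_h`` is set the locus
    is repairable: past that time enrichment relaxes toward 1 with time
    constant ``tau_off_h``. If ``caffeine_time_h`` is set (checkpoint-kinase
    inhibition), establishment freezes at its value at that time and decays
    mildly by ``decay_factor_per_h`` per hour. The two are mutually
    exclusive per locus.
    """

    emax_fold: float = 40.0
    tau_on_h: float = 1.0
    spread_kb: float = 30.0
    repair_time_h: float | None = None
    tau_off_h: float = 0.5
    caffeine_time_h: float | None = None
    decay_factor_per_h: float = 1.0
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.emax_fold < 1:
            raise ValueError("emax_fold must be >= 1")
        if self.tau_on_h <= 0 or self.tau_off_h <= 0:
            raise ValueError("time constants must be > 0")
        if self.spread_kb <= 0:
            raise ValueError("spread_kb must be > 0")
        if not 0.0 < self.decay_factor_per_h <= 1.0:
            raise ValueError("decay_factor_per_h must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.repair_time_h is not None and self.caffeine_time_h is not None:
            raise ValueError(
                "repair_time_h (repairable locus) and caffeine_time_h (persistent, "
                "kinase-inhibited locus) are mutually exclusive per locus"
            )


@dataclass(frozen=True)
class BlotSimConfig:
    """Generative parameters for a western/Southern band time course.

    The untreated level rises linearly from ``baseline`` to
    ``induction_fold * baseline`` by ``ref_time_h`` (default: the last
    simulated timepoint). The treated level follows the untreated level up to
    ``treat_time_h`` and then decays exponentially with ``half_life_h``.
    Lane intensity = level x loading_level x exposure x noise.
    """

    baseline: float = 1.0
    induction_fold: float = 1.0
    treat_time_h: float = 0.0
    half_life_h: float = 1.0
    loading_level: float = 1.0
    exposure: float = 1.0
    ref_time_h: float | None = None
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.induction_fold < 1:
            raise ValueError("induction_fold must be >= 1")
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")
        if self.baseline <= 0 or self.loading_level <= 0:
            raise ValueError("baseline and loading_level must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class FociSimConfig:
    """Generative parameters for per-nucleus repair-focus counts.

    Counts per nucleus are negative-binomial with mean
    ``mean_foci / fold_suppression`` and size (dispersion) parameter
    ``dispersion``; ``math.inf`` dispersion gives the Poisson limit.
    """

    mean_foci: float = 20.0
    dispersion: float = 5.0
    n_nuclei: int = 75
    n_experiments: int = 3
    fold_suppression: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_foci <= 0:
            raise ValueError("mean_foci must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_nuclei < 1 or self.n_experiments < 1:
            raise ValueError("n_nuclei and n_experiments must be >= 1")
        if self.fold_suppression < 1:
            raise ValueError("fold_suppression must be >= 1")

    @property
    def effective_mean(self) -> float:
        return self.mean_foci / self.fold_suppression


def default_panel() -> AmpliconPanel:
    """The standard single-sided amplicon series (0.7-30 kb) plus a control locus."""
    distances = (0.7, 2.0, 5.0, 8.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    entries = [Amplicon(f"amp_{d:g}kb", d) for d in distances]
    entries.append(Amplicon("control_locus", 0.0, is_control=True))
    return AmpliconPanel(tuple(entries))
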