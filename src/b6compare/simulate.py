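"""Synthetic multi-center phenotype studies and variant call sets.

The phenotype generator emulates the structure of a standardized broad
phenotyping pipeline run at several centers: each parameter is measured on
independent cohorts of both sub-strains at every center, with a
center-specific baseline offset, a strain effect expressed as a
standardized shift (numeric/time-course parameters) or a prevalence pair
(categorical parameters), and Gaussian measurement noise.  The variant
generator plants the exact artifact classes the hard-filter cascade is
built to remove — reference-shared calls, heterozygous calls (allele ratio
in [0.3, 0.8)), and calls at extreme depth — alongside clean true
variants, and returns the truth labels.

Both generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import VariantCall

CENTERS = ("HMGU", "ICS", "Harwell", "WTSI")
SEXES = ("male", "female")
STRAINS = ("B6N", "B6J")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterSpec:
    """One simulated phenotype parameter.

    ``effect`` is the standardized strain shift d = (mean_N − mean_J) /
    noise_sd for numeric and time-course parameters, or a
    (prevalence_N, prevalence_J) pair for categorical ones;
    ``center_prevalences`` optionally overrides the pair per center,
    emulating center-dependent penetrance.
    """

    name: str
    kind: str = "numeric"  # numeric | categorical | timecourse
    effect: float | tuple[float, float] = 0.0
    baseline: float = 0.0
    center_offsets: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    n_per_group: int = 20
    n_timepoints: int = 5
    affected_level: str = "affected"
    center_prevalences: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical", "timecourse"):
            raise ConfigError(f"{self.name}: unknown kind {self.kind!r}")
        if self.noise_sd <= 0:
            raise ConfigError(f"{self.name}: noise_sd must be positive")
        if self.n_per_group < 1:
            raise ConfigError(f"{self.name}: group size must be >= 1")
        if self.kind == "categorical":
            pairs = self.center_prevalences or (self.effect,)
            for pn, pj in pairs:
                if not (0 <= pn <= 1 and 0 <= pj <= 1):
                    raise ConfigError(f"{self.name}: prevalences must be in [0,1]")


@dataclass(frozen=True)
class StudyConfig:
    parameters: tuple[ParameterSpec, ...]
    centers: tuple[str, ...] = CENTERS
    sexes: tuple[str, ...] = SEXES
    seed: int = 0

    @property
    def n_centers(self) -> int:
        return len(self.centers)


def default_study_config(seed: int = 0) -> StudyConfig:
    """Study conditions parameterized from the published strain comparison.

    Visual acuity (N 0.314 vs J 0.399 cycles/degree, sd ≈ 0.043 → d ≈ −2),
    fundus vein count (4.8 vs 5.3, sd ≈ 1.1 → d ≈ −0.45), pulse rate
    (higher in N in all centers, d = +1), a glucose-tolerance time course
    (impaired in J → d = −1 on the N−J scale), fundus flecking prevalence
    (69.2 / 44.6 / 23.0 % in N depending on center vs 0 % in J), and a null
    parameter with no strain effect.
    """
    return StudyConfig(
        parameters=(
            ParameterSpec("visual_acuity", "numeric", effect=-2.0,
                          baseline=0.399, noise_sd=0.043),
            ParameterSpec("vein_count", "numeric", effect=-0.45,
                          baseline=5.3, noise_sd=1.1),
            ParameterSpec("pulse_rate", "numeric", effect=1.0,
                          baseline=600.0, noise_sd=30.0,
                          center_offsets=(0.0, 15.0, -10.0, 5.0)),
            ParameterSpec("glucose_auc", "timecourse", effect=-1.0,
                          baseline=10.0, noise_sd=2.0, n_timepoints=5),
            ParameterSpec("fundus_flecking", "categorical",
                          effect=(0.446, 0.0),
                          center_prevalences=((0.692, 0.0), (0.446, 0.0),
                                              (0.230, 0.0), (0.446, 0.0))),
            ParameterSpec("lens_opacity", "numeric", effect=0.0,
                          baseline=5.0, noise_sd=0.5),
        ),
        seed=seed,
    )


def generate_phenotype_study(config: StudyConfig) -> pd.DataFrame:
    """Simulate one multi-center study; one row per animal per parameter.

    Columns: center, parameter, kind, sex, strain, animal_id, group_key,
    value.  Time courses are emitted as comma-joined series.  Deterministic
    under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for p in config.parameters:
        offsets = p.center_offsets or (0.0,) * config.n_centers
        if len(offsets) != config.n_centers:
            raise ConfigError(f"{p.name}: need one center offset per center")
        for ci, center in enumerate(config.centers):
            for sex in config.sexes:
                for strain in STRAINS:
                    shift = 0.0
                    if p.kind != "categorical" and strain == "B6N":
                        shift = float(p.effect) * p.noise_sd
                    mean = p.baseline + offsets[ci] + shift
                    for a in range(p.n_per_group):
                        animal = f"{center}_{strain}_{sex[0]}{a:03d}"
                        if p.kind == "numeric":
                            value = f"{rng.normal(mean, p.noise_sd):.6g}"
                        elif p.kind == "timecourse":
                            series = rng.normal(mean, p.noise_sd, p.n_timepoints)
                            value = ",".join(f"{x:.6g}" for x in series)
                        else:
                            prev_n, prev_j = (
                                p.center_prevalences[ci]
                                if p.center_prevalences
                                else p.effect
                            )
                            prev = prev_n if strain == "B6N" else prev_j
                            hit = rng.random() < prev
                            value = p.affected_level if hit else "unaffected"
                        rows.append(
                            (center, p.name, p.kind, sex, strain, animal,
                             "default", value)
                        )
    return pd.DataFrame(
        rows,
        columns=["center", "parameter", "kind", "sex", "strain",
                 "animal_id", "group_key", "value"],
    )


def write_phenotype_tsv(df: pd.DataFrame, path, seed: int | None = None):
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# b6compare phenotype study, seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"value": str, "animal_id": str})


# ---------------------------------------------------------------------------
# variant call sets


@dataclass(frozen=True)
class VariantSimConfig:
    """Planted composition of a synthetic call set.

    The classes are disjoint by construction (each planted site gets a
    distinct genomic position).
    """

    n_true: int = 78
    n_reference_shared: int = 30
    n_heterozygous_artifacts: int = 10
    n_low_depth: int = 5
    n_high_depth: int = 7
    depth_range: tuple[int, int] = (3, 150)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_true, self.n_reference_shared,
                  self.n_heterozygous_artifacts, self.n_low_depth,
                  self.n_high_depth)
        if any(c < 0 for c in counts):
            raise ConfigError("planted class counts must be non-negative")
        lo, hi = self.depth_range
        if not 0 < lo <= hi:
            raise ConfigError("invalid depth_range")

    @property
    def total(self) -> int:
        return (self.n_true + self.n_reference_shared
                + self.n_heterozygous_artifacts + self.n_low_depth
                + self.n_high_depth)


_BASES = np.array(list("ACGT"))


def generate_variant_callsets(
    config: VariantSimConfig,
) -> tuple[list[VariantCall], list[VariantCall], pd.DataFrame]:
    """Simulate (focal calls, reference-set calls, truth labels).

    Reference-shared sites appear in both call sets with identical
    chrom/pos/ref/alt; heterozygous artifacts get an allele ratio uniform
    in [0.3, 0.8); depth artifacts fall outside ``depth_range``; true
    variants pass every filter.  The truth table labels each focal call.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.depth_range
    n = config.total
    chroms = np.sort(rng.integers(1, 20, n)).astype(str)
    # distinct positions guarantee disjoint planted classes
    positions = rng.choice(np.arange(1, 10_000_000), size=n, replace=False)
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    labels = np.repeat(
        ["true", "reference_shared", "heterozygous", "low_depth", "high_depth"],
        [config.n_true, config.n_reference_shared,
         config.n_heterozygous_artifacts, config.n_low_depth,
         config.n_high_depth],
    )
    rng.shuffle(labels)

    focal, reference, rows = [], [], []
    for i, label in enumerate(labels):
        if label == "heterozygous":
            ratio = float(rng.uniform(0.3, 0.8))
        else:
            ratio = float(rng.uniform(0.9, 1.0))
        if label == "low_depth":
            depth = int(rng.integers(0, lo))
        elif label == "high_depth":
            depth = int(rng.integers(hi + 1, hi + 101))
        else:
            depth = int(rng.integers(lo, hi + 1))
        call = VariantCall(str(chroms[i]), int(positions[i]),
                           str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]]),
                           depth, round(ratio, 4))
        focal.append(call)
        if label == "reference_shared":
            reference.append(call)
        rows.append((call.chrom, call.pos, call.ref, call.alt, label,
                     label == "true"))
    truth = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "class", "is_true"]
    )
    return focal, reference, truth
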