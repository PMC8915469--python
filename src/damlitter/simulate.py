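"""Synthetic dam-litter culture datasets with a known convergence structure.

The generator emulates the study design the pipeline targets: a small
number of dam-litter families sampled at birth and days 2, 30 and 60. Each
family carries a latent binary genus *profile* (per-genus Bernoulli
membership); every sample observes the family profile with independent
per-genus flips whose probability decays over time, so within-family
heterogeneity provably shrinks from T0 to T60. Meconium (the puppy's birth
rectal swab) gets an extra dropout of truly-present genera, mimicking the
sparse enteric flora seen at birth.

The expected per-genus disagreement between two samples of one family at
flip rate e is 2*e*(1-e); inverting this from the mean pairwise Hamming
disagreement recovers the flip rate (``estimate_flip_rate``), which is the
generator's parameter-recovery harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import (
    GrowthClass,
    IsolationRecord,
    MatrixType,
    PresenceMatrix,
    SampleMeta,
    SubjectRole,
    TimePoint,
    TIME_ORDER,
    ValidationError,
    write_records,
)

#: Genera of the kinds isolated from the study's samples (rectal swabs,
#: meconium, colostrum/milk and vaginal swabs).
DEFAULT_GENUS_POOL: tuple[str, ...] = (
    "Aerococcus", "Clostridium", "Enterobacter", "Enterococcus",
    "Escherichia", "Klebsiella", "Lactobacillus", "Leclercia",
    "Proteus", "Pseudomonas", "Psychrobacter", "Staphylococcus",
    "Streptococcus",
)

#: Time-decaying flip rates of the convergent preset.
CONVERGENT_FLIP_RATES: dict[str, float] = {
    "T0": 0.40, "T2": 0.30, "T30": 0.15, "T60": 0.10}

#: Constant flip rate of the null (no-convergence) preset.
NULL_FLIP_RATE = 0.25

_GROWTH_CHOICES = (GrowthClass.LOW, GrowthClass.MODERATE, GrowthClass.HIGH)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dam-litter dataset.

    Defaults mirror the emulated study's shape: 6 families, litter sizes
    3-8, four time points, flip rates decaying 0.40 -> 0.10.
    """

    n_families: int = 6
    litter_sizes: tuple[int, int] | Sequence[int] = (3, 8)
    genus_pool: Sequence[str] = DEFAULT_GENUS_POOL
    baseline_prevalence: float = 0.4
    flip_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(CONVERGENT_FLIP_RATES))
    meconium_dropout: float = 0.5
    include_dam_matrices: bool = True
    shared_core: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        if not self.genus_pool:
            raise ValidationError("genus_pool must be non-empty")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValidationError("baseline_prevalence must be in (0, 1)")
        if not 0.0 <= self.meconium_dropout < 1.0:
            raise ValidationError("meconium_dropout must be in [0, 1)")
        for tp in TIME_ORDER:
            e = self.flip_rates.get(tp.value)
            if e is None or not 0.0 <= e <= 0.5:
                raise ValidationError(
                    f"flip rate for {tp.value} must be given and within [0, 0.5]")
        unknown = set(self.shared_core) - set(self.genus_pool)
        if unknown:
            raise ValidationError(
                "shared_core genera missing from pool: " + ", ".join(sorted(unknown)))

    @classmethod
    def convergent(cls, seed: int = 0, **kwargs) -> "SyntheticConfig":
        """The default preset: flip rates decay over time, so heterogeneity
        shrinks from birth to day 60."""
        return cls(seed=seed, **kwargs)

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "SyntheticConfig":
        """No-convergence preset: constant flip rate at every time point and
        no meconium dropout, so every time point is exchangeable (the
        type-I-error reference condition)."""
        kwargs.setdefault("flip_rates",
                          {tp.value: NULL_FLIP_RATE for tp in TIME_ORDER})
        kwargs.setdefault("meconium_dropout", 0.0)
        return cls(seed=seed, **kwargs)


def _draw_litter_size(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    ls = cfg.litter_sizes
    if len(ls) == 2 and isinstance(ls, tuple):
        lo, hi = ls
        return int(rng.integers(lo, hi + 1))
    return int(rng.choice(list(ls)))


def generate(
    config: SyntheticConfig,
) -> tuple[list[SampleMeta], list[IsolationRecord], dict]:
    """Generate one synthetic dataset: metadata, isolation records and the
    ground truth (family profiles and flip rates). Fully reproducible from
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genera = list(config.genus_pool)
    g = len(genera)
    core = np.isin(genera, list(config.shared_core))

    samples: list[SampleMeta] = []
    records: list[IsolationRecord] = []
    profiles: dict[str, list[int]] = {}

    def emit(meta: SampleMeta, profile: np.ndarray, eps: float,
             dropout: float = 0.0) -> None:
        flips = rng.random(g) < eps
        pattern = profile ^ flips
        if dropout > 0:
            lost = (rng.random(g) < dropout) & (pattern == 1)
            pattern = pattern & ~lost
        samples.append(meta)
        for gi in np.flatnonzero(pattern):
            growth = _GROWTH_CHOICES[rng.integers(0, 3)]
            records.append(IsolationRecord(meta.sample_id, genera[gi],
                                           species=None, growth=growth))

    for f in range(config.n_families):
        fam = f"F{f + 1:02d}"
        profile = (rng.random(g) < config.baseline_prevalence) | core
        profile = profile.astype(bool)
        profiles[fam] = profile.astype(int).tolist()
        dam = f"{fam}-dam"
        litter = _draw_litter_size(config, rng)

        for tp in TIME_ORDER:
            eps = config.flip_rates[tp.value]
            emit(SampleMeta(f"{dam}-rectal-{tp.value}", fam, dam,
                            SubjectRole.DAM, MatrixType.RECTAL, tp),
                 profile, eps)
        if config.include_dam_matrices:
            e0 = config.flip_rates["T0"]
            for tp in (TimePoint.T0, TimePoint.T2):
                emit(SampleMeta(f"{dam}-vaginal-{tp.value}", fam, dam,
                                SubjectRole.DAM, MatrixType.VAGINAL, tp),
                     profile, e0)
                emit(SampleMeta(f"{dam}-mammary-{tp.value}", fam, dam,
                                SubjectRole.DAM, MatrixType.MAMMARY_SECRETION, tp),
                     profile, e0)
        for p in range(litter):
            pup = f"{fam}-p{p + 1}"
            emit(SampleMeta(f"{pup}-meconium-T0", fam, pup,
                            SubjectRole.PUPPY, MatrixType.MECONIUM, TimePoint.T0),
                 profile, config.flip_rates["T0"], dropout=config.meconium_dropout)
            for tp in (TimePoint.T2, TimePoint.T30, TimePoint.T60):
                emit(SampleMeta(f"{pup}-rectal-{tp.value}", fam, pup,
                                SubjectRole.PUPPY, MatrixType.RECTAL, tp),
                     profile, config.flip_rates[tp.value])

    truth = {
        "seed": config.seed,
        "genus_pool": genera,
        "flip_rates": dict(config.flip_rates),
        "meconium_dropout": config.meconium_dropout,
        "baseline_prevalence": config.baseline_prevalence,
        "profiles": profiles,
    }
    return samples, records, truth


def write_synthetic(
    config: SyntheticConfig,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Emit one dataset as the long-format CSV the reader consumes, plus a
    truth JSON (profiles, flip rates, seed) for recovery tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, records, truth = generate(config)
    csv_path = out / "records.csv"
    truth_path = out / "truth.json"
    write_records(samples, records, csv_path)
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return csv_path, truth_path


def estimate_flip_rate(
    m: PresenceMatrix,
    samples: Sequence[SampleMeta],
    time_point: TimePoint | str,
    family_id: str | None = None,
    matrix_filter: Iterable[MatrixType] | None = None,
) -> float:
    """Recover the per-genus flip rate from observed pattern disagreement.

    The mean pairwise Hamming disagreement fraction h among samples of one
    family satisfies E[h] = 2e(1-e); the estimator inverts this and clips
    to [0, 0.5]. With ``family_id=None`` disagreements are pooled over all
    families (pair-weighted) before the single inversion, which avoids the
    bias of inverting noisy per-family means near the flat point h = 0.5.
    """
    tp = TimePoint(time_point)
    allowed = set(matrix_filter) if matrix_filter is not None else None
    meta = {s.sample_id: s for s in samples}
    pos = {sid: i for i, sid in enumerate(m.sample_ids)}

    total_diff = 0.0
    total_pairs = 0
    fams = {family_id} if family_id else {s.family_id for s in samples}
    for fam in sorted(fams):
        ids = [
            s.sample_id for s in samples
            if s.family_id == fam and s.time_point is tp
            and (allowed is None or s.matrix in allowed)
            and s.sample_id in pos
        ]
        if len(ids) < 2:
            continue
        x = m.values[[pos[i] for i in ids]].astype(int)
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                total_diff += float(np.mean(x[i] != x[j]))
                total_pairs += 1
    if total_pairs == 0:
        raise ValidationError(
            f"fewer than 2 samples at {tp.value}"
            + (f" in family {family_id}" if family_id else ""))
    h = total_diff / total_pairs
    if h > 0.5:
        import logging
        logging.getLogger(__name__).warning(
            "mean disagreement %.3f exceeds 0.5; flip rate clipped to 0.5", h)
        return 0.5
    return float((1.0 - np.sqrt(1.0 - 2.0 * h)) / 2.0)
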