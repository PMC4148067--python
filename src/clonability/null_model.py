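"""Matched random clone libraries and empirical enrichment significance.

The control for every clone-library statistic is a resampling null: a
random library with the same number of clones, lengths drawn from the
observed library's mean and standard deviation, placed uniformly on the
genome.  Enrichment of an observed statistic is then assessed against the
distribution of the same statistic over many such random libraries, with
an add-one-smoothed empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence

import numpy as np

from .annotation_io import CloneRecord
from .intervals import ChromSizes, GenomicInterval

_LENGTH_FLOOR_DEFAULT = 500  # bp; avoids degenerate near-zero clones


@dataclass(frozen=True)
class LengthModel:
    """Clone-count and length distribution of a library to be matched."""

    n: int
    mean: float
    sd: float
    floor: int = _LENGTH_FLOOR_DEFAULT

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mean <= 0:
            raise ValueError("mean length must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed statistic vs its matched-random-library null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    replicates: int
    seed: int
    alternative: str = "greater"


def fit_length_model(clones: Sequence[CloneRecord], floor: int = _LENGTH_FLOOR_DEFAULT) -> LengthModel:
    """n, mean and SD (n−1 denominator) of the clones' lengths."""
    if not clones:
        raise ValueError("cannot fit a length model to an empty library")
    lengths = np.array([c.length for c in clones], dtype=float)
    sd = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    return LengthModel(n=len(lengths), mean=float(lengths.mean()), sd=sd, floor=floor)


def sample_random_library(
    sizes: ChromSizes,
    model: LengthModel,
    seed: int | np.random.Generator,
) -> List[CloneRecord]:
    """Draw a matched random clone library.

    Lengths ~ Normal(mean, sd) truncated by redraw to [floor, longest
    chromosome] and rounded to integers; chromosomes are chosen with
    probability proportional to their length (genome-uniform placement)
    and starts uniformly so the clone fits.  Clones may overlap one
    another.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(sizes)
    chrom_lens = np.array([sizes[c] for c in chroms], dtype=float)
    longest = int(chrom_lens.max())
    if model.mean > longest:
        raise ValueError(
            f"mean clone length {model.mean:.0f} exceeds the longest chromosome ({longest} bp)"
        )
    lo = max(model.floor, 1)
    # the truncation window must carry probability mass, or redraw never ends
    if model.sd == 0:
        if not (lo <= model.mean <= longest):
            raise ValueError(
                f"degenerate length {model.mean:.0f} outside [{lo}, {longest}]"
            )
    elif model.mean + 6 * model.sd < lo or model.mean - 6 * model.sd > longest:
        raise ValueError(
            f"length model N({model.mean:.0f}, {model.sd:.0f}) has no mass "
            f"inside [{lo}, {longest}]"
        )
    lengths = np.empty(model.n, dtype=np.int64)
    need = np.ones(model.n, dtype=bool)
    while need.any():
        draw = rng.normal(model.mean, model.sd, size=int(need.sum()))
        draw = np.rint(draw).astype(np.int64)
        ok = (draw >= lo) & (draw <= longest)
        idx = np.flatnonzero(need)[ok]
        lengths[idx] = draw[ok]
        need[idx] = False
    probs = chrom_lens / chrom_lens.sum()
    chrom_idx = np.empty(model.n, dtype=np.int64)
    need = np.ones(model.n, dtype=bool)
    while need.any():  # redraw clones landing on a chromosome too short for them
        k = int(need.sum())
        draw = rng.choice(len(chroms), size=k, p=probs)
        ok = chrom_lens[draw] >= lengths[need]
        idx = np.flatnonzero(need)[ok]
        chrom_idx[idx] = draw[ok]
        need[idx] = False
    room = chrom_lens.astype(np.int64)[chrom_idx] - lengths + 1
    starts = (rng.random(model.n) * room).astype(np.int64)
    return [
        CloneRecord(
            f"rand{i}", "cosmid",
            GenomicInterval(chroms[ci], int(s), int(s + ln)),
        )
        for i, (ci, s, ln) in enumerate(zip(chrom_idx, starts, lengths))
    ]


def enrichment_test(
    observed_clones: Sequence[CloneRecord],
    feature_stat: Callable[[Sequence[CloneRecord]], float],
    sizes: ChromSizes,
    model: LengthModel | None = None,
    replicates: int = 200,
    seed: int = 0,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Score an observed library statistic against matched random libraries.

    ``feature_stat`` maps a clone library to a number (e.g. mean
    DNA-transposon percent, ncRNA genes per MB).  The empirical p-value
    uses add-one smoothing: p = (1 + #{null ≥ observed}) / (1 + R) for the
    right tail; 'less' mirrors it and 'two-sided' doubles the smaller tail
    (capped at 1).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"bad alternative {alternative!r}")
    if model is None:
        model = fit_length_model(observed_clones)
    rng = np.random.default_rng(seed)
    observed = float(feature_stat(observed_clones))
    null = np.empty(replicates)
    for r in range(replicates):
        null[r] = feature_stat(sample_random_library(sizes, model, rng))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if replicates > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p_ge = (1 + int((null >= observed).sum())) / (1 + replicates)
    p_le = (1 + int((null <= observed).sum())) / (1 + replicates)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2 * min(p_ge, p_le))
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_value=p,
        replicates=replicates,
        seed=seed if isinstance(seed, int) else -1,
        alternative=alternative,
    )
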