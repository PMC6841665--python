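"""Goodness-of-fit tests of litter genotype counts against Mendelian ratios.

The default statistic is the uncorrected Pearson chi-squared
``sum((obs - exp)^2 / exp)`` with ``exp`` proportional to the expected
ratio weights, df = categories - 1.  A Yates continuity correction is
available for two categories, and an exact multinomial test for small
litters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeCounts:
    categories: list[str]
    observed: list[int]
    expected_ratio: list[float]

    def __post_init__(self) -> None:
        if not (len(self.categories) == len(self.observed) == len(self.expected_ratio)):
            raise ValueError("categories/observed/expected_ratio lengths differ")
        if any(o < 0 for o in self.observed):
            raise ValueError("negative observed count")
        if sum(self.observed) <= 0:
            raise ValueError("no observations")
        if any(w <= 0 for w in self.expected_ratio):
            raise ValueError("expected ratio weights must be positive")


def mendelian_test(
    counts: GenotypeCounts,
    yates: bool = False,
    exact: bool = False,
) -> tuple[float, int, float]:
    """Chi-squared (or exact multinomial) test against the expected ratio.

    Returns ``(chi2, df, p)``; for the exact test chi2 is still reported
    as the observed statistic and ``p`` is the multinomial probability of
    outcomes at least as extreme (by probability ordering).
    """
    obs = np.asarray(counts.observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 genotype categories")
    w = np.asarray(counts.expected_ratio, dtype=float)
    n = obs.sum()
    exp = n * w / w.sum()
    if (exp == 0).any():
        raise ValueError("expected count of zero in some category")
    if (exp < 5).any():
        warnings.warn("expected count < 5 in some category; chi-squared approximation is weak")

    diff = np.abs(obs - exp)
    if yates:
        if obs.size != 2:
            raise ValueError("Yates correction applies to 2 categories only")
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / exp).sum())
    df = obs.size - 1

    if exact:
        p = _exact_multinomial_p(obs.astype(int), w / w.sum())
    else:
        p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _exact_multinomial_p(obs: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial P: total probability of outcomes no more likely
    than the observed one (probability-ordering convention)."""
    n = int(obs.sum())
    k = obs.size
    p_obs = stats.multinomial.pmf(obs, n, probs)
    total = 0.0
    for combo in combinations_with_replacement(range(k), n):
        vec = np.bincount(np.array(combo), minlength=k)
        p = stats.multinomial.pmf(vec, n, probs)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return float(min(total, 1.0))


def parse_ratio(text: str) -> list[float]:
    """Parse an expected-ratio string such as ``"1:2:1"``."""
    parts = [float(x) for x in str(text).split(":")]
    if any(p <= 0 for p in parts):
        raise ValueError(f"ratio weights must be positive: {text!r}")
    return parts


def genotype_percentages(counts: GenotypeCounts) -> dict[str, float]:
    """Observed percentage of each genotype among surviving pups."""
    n = sum(counts.observed)
    return {c: 100.0 * o / n for c, o in zip(counts.categories, counts.observed)}


def read_litter_table(path: str | Path) -> list[GenotypeCounts]:
    """Read a litter TSV: columns ``cross``, ``genotypes`` (comma-separated
    label=count pairs), ``ratio`` (e.g. ``1:2:1``)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        cats, obs = [], []
        for pair in str(r["genotypes"]).split(","):
            label, count = pair.split("=")
            cats.append(label.strip())
            obs.append(int(count))
        out.append(GenotypeCounts(cats, obs, parse_ratio(r["ratio"])))
    return out


def litter_report(litters: Sequence[GenotypeCounts], yates: bool = False) -> pd.DataFrame:
    rows = []
    for gc in litters:
        chi2, df_, p = mendelian_test(gc, yates=yates)
        rows.append(
            {
                "genotypes": ",".join(f"{c}={o}" for c, o in zip(gc.categories, gc.observed)),
                "ratio": ":".join(str(int(w)) if w == int(w) else str(w) for w in gc.expected_ratio),
                "n": sum(gc.observed),
                "chi2": chi2,
                "df": df_,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
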