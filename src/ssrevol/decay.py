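"""Exponential decay rates and relative-abundance contrasts.

Assuming a steady loss of microsatellite loci over the divergence time
``t`` (default 6 million years, the median progenitor/tetraploid estimate),
a conserved fraction ``C`` maps to the decay rate

    lambda = -ln(C) / t        [per million years]

so C = 1 gives lambda = 0 and complete loss (C = 0) is flagged as a
sentinel rather than an infinite rate.  "Relative decay" contrasts each
motif class against the pooled overall estimate — lambda_k - lambda_all
for rates and (1 - C_k) - (1 - C_all) for loss fractions, so a class
decaying at the overall rate sits on the y = 0 line.  Relative abundance
compares per-class densities between a focal and a reference genome as
(focal - reference) / reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayEstimate",
    "decay_rate",
    "estimate_decay",
    "relative_decay",
    "relative_abundance",
    "compare_groups",
]


@dataclass
class DecayEstimate:
    """Per-class decay summary; ``complete_loss`` flags C = 0 sentinels."""

    label: str
    conserved_fraction: float
    divergence_time: float
    decay_rate: float
    relative_decay: float = float("nan")
    relative_loss: float = float("nan")
    complete_loss: bool = False


def decay_rate(conserved_fraction: float, divergence_time: float = 6.0
               ) -> float:
    """lambda = -ln(C)/t for 0 < C <= 1."""
    if divergence_time <= 0:
        raise ValueError("divergence_time must be > 0")
    if not 0.0 < conserved_fraction <= 1.0:
        raise ValueError("conserved_fraction must be in (0, 1]")
    return -math.log(conserved_fraction) / divergence_time


def estimate_decay(proportions: Mapping[str, float],
                   overall: float,
                   divergence_time: float = 6.0) -> list[DecayEstimate]:
    """Decay estimates for each class plus the pooled ``all`` contrast.

    ``proportions`` maps class label -> conserved fraction; ``overall`` is
    the pooled conserved fraction.  Classes with C = 0 are flagged as
    complete loss and excluded from rate contrasts.
    """
    lam_all = decay_rate(overall, divergence_time)
    out = [DecayEstimate("all", overall, divergence_time, lam_all,
                         relative_decay=0.0, relative_loss=0.0)]
    for label, c in proportions.items():
        if c == 0.0:
            out.append(DecayEstimate(label, 0.0, divergence_time,
                                     float("nan"), complete_loss=True))
            continue
        lam = decay_rate(c, divergence_time)
        out.append(DecayEstimate(
            label, c, divergence_time, lam,
            relative_decay=lam - lam_all,
            relative_loss=(1.0 - c) - (1.0 - overall)))
    return out


def relative_decay(estimates: Sequence[DecayEstimate],
                   overall: DecayEstimate) -> list[DecayEstimate]:
    """Fill the contrast fields of per-class estimates against ``overall``."""
    out = []
    for e in estimates:
        if e.complete_loss:
            out.append(e)
            continue
        out.append(DecayEstimate(
            e.label, e.conserved_fraction, e.divergence_time, e.decay_rate,
            relative_decay=e.decay_rate - overall.decay_rate,
            relative_loss=(1.0 - e.conserved_fraction)
            - (1.0 - overall.conserved_fraction)))
    return out


def relative_abundance(focal: Mapping[str, float],
                       reference: Mapping[str, float]) -> pd.DataFrame:
    """(focal - reference)/reference per class (densities in loci/Mb).

    Classes absent or zero in the reference are flagged undefined.
    """
    rows = []
    for label in focal:
        f = focal[label]
        r = reference.get(label, 0.0)
        if r <= 0:
            rows.append({"label": label, "focal_density": f,
                         "reference_density": r,
                         "relative_abundance": float("nan"),
                         "defined": False})
        else:
            rows.append({"label": label, "focal_density": f,
                         "reference_density": r,
                         "relative_abundance": (f - r) / r,
                         "defined": True})
    return pd.DataFrame(rows)


def compare_groups(groups: Mapping[str, Sequence[float]],
                   test: str = "kruskal_wallis") -> dict:
    """Nonparametric comparison of value groups.

    ``friedman`` treats the groups as repeated measures over a complete
    block design (all groups must have equal length); ``kruskal_wallis``
    is the unpaired rank test; ``pairwise_t`` additionally returns a
    two-sided p-value matrix of all pairwise t-tests.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if test == "friedman":
        sizes = {len(d) for d in data}
        if len(sizes) != 1:
            raise ValueError("friedman requires a complete block design "
                             "(equal group lengths)")
        if all(np.ptp(np.array([d[i] for d in data])) == 0
               for i in range(len(data[0]))):
            return {"test": test, "statistic": 0.0, "p_value": 1.0}
        s, p = stats.friedmanchisquare(*data)
        return {"test": test, "statistic": float(s), "p_value": float(p)}
    if test == "kruskal_wallis":
        if all(np.array_equal(d, data[0]) for d in data):
            return {"test": test, "statistic": 0.0, "p_value": 1.0}
        s, p = stats.kruskal(*data)
        return {"test": test, "statistic": float(s), "p_value": float(p)}
    if test == "pairwise_t":
        mat = pd.DataFrame(np.nan, index=names, columns=names)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    _, p = stats.ttest_ind(data[i], data[j])
                    mat.loc[a, b] = mat.loc[b, a] = float(p)
        return {"test": test, "pairwise_p": mat}
    raise ValueError(f"unknown test {test!r}")
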