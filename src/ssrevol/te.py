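"""Transposable-element abundance near perfect vs imperfect microsatellites.

A TE is "near" a locus when its interval overlaps the locus extended by a
500 nt flank on both sides (half-open windows, overlap of at least one
base); each (locus, TE) pair counts once, so a TE shared by two loci
contributes to both.  Chromosomes are treated as independent segments and
the per-chromosome locus and nearby-TE counts are correlated (Pearson)
separately for perfect (no mismatch) and imperfect (mismatch >= 1) loci.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import MicrosatelliteLocus
from .simulate import TEInterval

__all__ = ["count_tes_near_loci", "correlate_te_repeats"]


def count_tes_near_loci(loci: Sequence[MicrosatelliteLocus],
                        te_intervals: Sequence[TEInterval],
                        flank: int = 500) -> pd.DataFrame:
    """Per-chromosome counts of loci and of TEs near them.

    Columns: ``chromosome, n_perfect_loci, n_imperfect_loci,
    n_te_near_perfect, n_te_near_imperfect``.
    """
    te_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {t.chromosome for t in te_intervals}:
        tes = [t for t in te_intervals if t.chromosome == chrom]
        starts = np.sort(np.array([t.start for t in tes]))
        ends = np.sort(np.array([t.end for t in tes]))
        te_by_chrom[chrom] = (starts, ends)
    chroms = sorted({l.chromosome for l in loci}
                    | {t.chromosome for t in te_intervals})
    rows = []
    for chrom in chroms:
        starts, ends = te_by_chrom.get(chrom, (np.zeros(0), np.zeros(0)))
        rec = {"chromosome": chrom, "n_perfect_loci": 0,
               "n_imperfect_loci": 0, "n_te_near_perfect": 0,
               "n_te_near_imperfect": 0}
        for loc in loci:
            if loc.chromosome != chrom:
                continue
            w0 = max(0, loc.start - flank)
            w1 = loc.end + flank
            # TEs overlapping [w0, w1): start < w1 and end > w0
            n_near = int(np.searchsorted(starts, w1, side="left")
                         - np.searchsorted(ends, w0, side="right"))
            if loc.is_perfect:
                rec["n_perfect_loci"] += 1
                rec["n_te_near_perfect"] += n_near
            else:
                rec["n_imperfect_loci"] += 1
                rec["n_te_near_imperfect"] += n_near
        rows.append(rec)
    return pd.DataFrame(rows)


def correlate_te_repeats(records: pd.DataFrame) -> dict[str, dict]:
    """Pearson r (+ linear fit) between locus counts and nearby-TE counts
    across chromosomes, separately for perfect and imperfect loci."""
    if len(records) < 3:
        raise ValueError("need at least 3 chromosomes")
    out = {}
    for label, xcol, ycol in (
            ("perfect", "n_perfect_loci", "n_te_near_perfect"),
            ("imperfect", "n_imperfect_loci", "n_te_near_imperfect")):
        x = records[xcol].to_numpy(dtype=float)
        y = records[ycol].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[label] = {"r": float("nan"), "p_value": float("nan"),
                          "slope": float("nan"), "intercept": float("nan"),
                          "defined": False}
            continue
        r, p = stats.pearsonr(x, y)
        fit = stats.linregress(x, y)
        out[label] = {"r": float(r), "p_value": float(p),
                      "slope": float(fit.slope),
                      "intercept": float(fit.intercept), "defined": True}
    return out
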