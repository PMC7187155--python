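"""Grouped IQR outlier exclusion with whole-sample discard semantics.

Relative opsin proportions are filtered per (gene x species x rearing
light) group: values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] flag their
sample, and a sample flagged for any one gene is discarded entirely,
because each proportion is defined relative to the other three genes.
Quartiles use linear interpolation between order statistics (numpy's
default, R type 7); a single pass is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpcr import GENES

IQR_MULTIPLIER = 1.5
MIN_GROUP_SIZE = 4


@dataclass
class Removal:
    sample_id: str
    genes: list
    group: tuple
    bounds: dict  # gene -> (lower, upper)


@dataclass
class FilterReport:
    n_input: int
    n_removed: int
    removals: list = field(default_factory=list)
    skipped_groups: list = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.removals:
            for g in r.genes:
                lo, hi = r.bounds[g]
                rows.append({"sample": r.sample_id, "gene": g,
                             "species": r.group[0], "rearing_light": r.group[1],
                             "lower": lo, "upper": hi})
        return pd.DataFrame(rows,
                            columns=["sample", "gene", "species",
                                     "rearing_light", "lower", "upper"])


def iqr_filter(profiles: pd.DataFrame,
               grouping: tuple = ("species", "rearing_light"),
               multiplier: float = IQR_MULTIPLIER):
    """One-pass grouped IQR filter over a profile table.

    ``profiles`` needs a ``sample`` column, ``prop_<gene>`` columns for
    the four opsins and the grouping metadata columns.  Returns
    (surviving profiles, FilterReport).  Groups smaller than four
    samples are skipped with a warning (their quartiles are unstable).
    """
    df = profiles.reset_index(drop=True)
    flagged = {}  # sample -> Removal
    skipped = []
    for key, grp in df.groupby(list(grouping), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if len(grp) < MIN_GROUP_SIZE:
            skipped.append(key)
            warnings.warn(
                f"group {key}: only {len(grp)} samples, IQR filter skipped",
                stacklevel=2)
            continue
        for gene in GENES:
            vals = grp[f"prop_{gene}"].to_numpy(dtype=float)
            q1, q3 = np.quantile(vals, [0.25, 0.75])
            iqr = q3 - q1
            lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
            out = (vals < lo) | (vals > hi)
            for sample in grp.loc[grp.index[out], "sample"]:
                rem = flagged.setdefault(
                    str(sample), Removal(str(sample), [], key, {}))
                rem.genes.append(gene)
                rem.bounds[gene] = (float(lo), float(hi))
    keep = ~df["sample"].astype(str).isin(flagged)
    report = FilterReport(n_input=len(df), n_removed=len(flagged),
                          removals=sorted(flagged.values(),
                                          key=lambda r: r.sample_id),
                          skipped_groups=skipped)
    return df[keep].reset_index(drop=True), report
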