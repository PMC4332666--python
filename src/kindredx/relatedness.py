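"""Pairwise relatedness by shared-variant identity, kindred validation, and
population-stratification metrics.

Identity between two haploid call sets is
``2 * |A ∩ B| / (|A| + |B|)`` with the intersection keyed on the full
(chrom, pos, ref, alt) variant key.  Declared kindred pairs are expected to
be each other's highest-identity match, standing out as box-whisker outliers
of their own identity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calls import SampleCallSet
from .cohort import CohortDesign
from .errors import UndefinedStatisticError


def identity(calls_a: SampleCallSet, calls_b: SampleCallSet) -> float:
    """Fraction of variants identical between two samples, in [0, 1]."""
    na, nb = len(calls_a), len(calls_b)
    if na + nb == 0:
        raise UndefinedStatisticError("identity undefined for two empty call sets")
    shared = len(calls_a.key_set & calls_b.key_set)
    return 2.0 * shared / (na + nb)


@dataclass
class IdentityMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal

    def loc(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def identity_matrix(cohort: Sequence[SampleCallSet]) -> IdentityMatrix:
    if len(cohort) < 2:
        raise UndefinedStatisticError("identity matrix needs at least two samples")
    ids = [cs.sample_id for cs in cohort]
    n = len(cohort)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = identity(cohort[i], cohort[j])
    return IdentityMatrix(sample_ids=ids, values=m)


def validate_pairs(
    matrix: IdentityMatrix, design: CohortDesign, whisker: float = 1.5
) -> pd.DataFrame:
    """Check that each declared kindred pair is its own best identity match.

    A sample's best match is flagged as an outlier when its identity exceeds
    Q3 + ``whisker``·IQR of that sample's identity distribution (the Tukey
    box-whisker convention).  ``consistent`` is False when a declared kin is
    not the best match, or when a sporadic sample has an outlying best match.
    """
    rows = []
    ids = matrix.sample_ids
    for i, sid in enumerate(ids):
        others = np.array([matrix.values[i, j] for j in range(len(ids)) if j != i])
        other_ids = [ids[j] for j in range(len(ids)) if j != i]
        best_idx = int(np.argmax(others))
        best_match = other_ids[best_idx]
        best_val = float(others[best_idx])
        q1, q3 = np.percentile(others, [25, 75])
        is_outlier = best_val > q3 + whisker * (q3 - q1)
        declared = design.kin_of(sid)
        is_declared_kin = declared is not None and best_match == declared
        consistent = is_declared_kin if declared is not None else not is_outlier
        rows.append(
            {
                "sample_id": sid,
                "best_match": best_match,
                "best_identity": best_val,
                "declared_kin": declared or "-",
                "is_declared_kin": is_declared_kin,
                "is_outlier": bool(is_outlier),
                "consistent": bool(consistent),
            }
        )
    return pd.DataFrame(rows)


def stratification_metrics(
    cohort: Sequence[SampleCallSet], panel: "pd.DataFrame | object"
) -> pd.DataFrame:
    """Per-sample deviation from the cohort genotype mean plus reference-
    population allele-frequency loads.

    ``panel`` must provide per-variant frequencies for two reference
    populations in columns ``freq_pop_a`` and ``freq_pop_b`` (a
    ReferencePanel or its records frame).  The cohort genotype mean at a
    site is the fraction of samples carrying the alt (haploid carriers);
    ``rss_sd`` is each sample's residual sum of squares versus that mean,
    expressed in cohort standard-deviation units.
    """
    records = getattr(panel, "records", panel)
    site_freqs = {
        (r.chrom, r.pos, r.ref, r.alt): (float(r.freq_pop_a), float(r.freq_pop_b))
        for r in records.itertuples()
    }
    all_keys = sorted(set().union(*(cs.key_set for cs in cohort)))
    key_idx = {k: i for i, k in enumerate(all_keys)}
    g = np.zeros((len(cohort), len(all_keys)))
    for i, cs in enumerate(cohort):
        for k in cs.key_set:
            g[i, key_idx[k]] = 1.0
    mean = g.mean(axis=0)
    rss = ((g - mean) ** 2).sum(axis=1)
    sd = rss.std()
    rss_sd = (rss - rss.mean()) / sd if sd > 0 else np.zeros_like(rss)
    rows = []
    for i, cs in enumerate(cohort):
        matched = [site_freqs[k] for k in cs.key_set if k in site_freqs]
        if matched:
            ea = float(np.mean([m[0] for m in matched]))
            aa = float(np.mean([m[1] for m in matched]))
            flagged = False
        else:
            ea = aa = float("nan")
            flagged = True
        rows.append(
            {
                "sample_id": cs.sample_id,
                "rss": float(rss[i]),
                "rss_sd": float(rss_sd[i]),
                "ea_metric": ea,
                "aa_metric": aa,
                "n_panel_matched": len(matched),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
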