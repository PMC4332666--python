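"""Reference variant panels, the database subtraction filters, and the
female-carrier minor-allele-frequency cutoff model.

The cutoff model asks: for a variant observed ``n`` times among M male and
2F female X chromosomes (F females, each with two), what is the probability
that every copy sits in a distinct heterozygous female carrier and none in a
male?  An X-linked recessive pathological variant can hide in unaffected
female carriers but not in unaffected hemizygous males, so an allele count
at which that probability is small is safe to subtract.
"""

from __future__ import annotations

from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .calls import SampleCallSet, VariantKey
from .cohort import REJECT, RETAIN, LedgerEntry
from .errors import ConfigurationError, DomainError, PanelIntegrityError

CLIN_SIG_VALUES = ("none", "probable-pathogenic", "pathogenic", "other")
PATHOGENIC = frozenset({"probable-pathogenic", "pathogenic"})

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


class ReferencePanel:
    """A population variant table with sex-resolved counts and clinical codes.

    ``records`` is a DataFrame keyed by (chrom, pos, ref, alt); optional
    columns used by the filters: ``maf``, ``allele_count``,
    ``male_carrier_count``, ``female_only``, ``hemizygous_annotated``,
    ``clin_sig``, ``freq_pop_a``, ``freq_pop_b``.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        source: str = "",
        n_male_chr: int | None = None,
        n_female_individuals: int | None = None,
    ) -> None:
        missing = [c for c in KEY_COLUMNS if c not in records.columns]
        if missing:
            raise ConfigurationError(f"panel records lack key columns {missing}")
        if records.duplicated(KEY_COLUMNS).any():
            raise ConfigurationError("panel records contain duplicate variant keys")
        self.records = records.reset_index(drop=True)
        self.source = source
        self.n_male_chr = n_male_chr
        self.n_female_individuals = n_female_individuals
        self._keys: frozenset[VariantKey] | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def key_set(self) -> frozenset[VariantKey]:
        if self._keys is None:
            r = self.records
            self._keys = frozenset(
                zip(r["chrom"], r["pos"].astype(int), r["ref"], r["alt"])
            )
        return self._keys

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.key_set

    def subset(self, mask) -> "ReferencePanel":
        return ReferencePanel(
            self.records[mask].copy(),
            source=self.source,
            n_male_chr=self.n_male_chr,
            n_female_individuals=self.n_female_individuals,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        source: str = "",
        n_male_chr: int | None = None,
        n_female_individuals: int | None = None,
    ) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df, source=source, n_male_chr=n_male_chr, n_female_individuals=n_female_individuals)


def carrier_probability(
    n_copies: int,
    n_male_chr: int,
    n_female_individuals: int,
    model: str = "carrier",
) -> float:
    """Probability that all ``n_copies`` of a variant land on female
    chromosomes with no female carrying two (heterozygous carriers only).

    Under random placement without replacement of ``n`` copies among
    ``M + 2F`` chromosomes this is ``C(F, n) * 2**n / C(M + 2F, n)``; it is
    0 whenever ``n > F``.  ``model="chromosome"`` gives the plain
    all-copies-on-female-chromosomes probability ``C(2F, n) / C(M + 2F, n)``
    (homozygous females allowed) instead.
    """
    if n_copies < 0 or n_male_chr <= 0 or n_female_individuals <= 0:
        raise DomainError("counts must be non-negative (populations positive)")
    M, F = n_male_chr, n_female_individuals
    total = M + 2 * F
    if n_copies > total:
        raise DomainError(f"n_copies {n_copies} exceeds total chromosomes {total}")
    if model == "carrier":
        if n_copies > F:
            return 0.0
        return comb(F, n_copies) * 2**n_copies / comb(total, n_copies)
    if model == "chromosome":
        if n_copies > 2 * F:
            return 0.0
        return comb(2 * F, n_copies) / comb(total, n_copies)
    raise DomainError(f"unknown model {model!r}")


def min_count_for_cutoff(
    p_max: float = 0.01,
    n_male_chr: int = 525,
    n_female_individuals: int = 567,
    model: str = "carrier",
) -> int:
    """Smallest allele count whose female-carrier probability is <= p_max.

    Returns ``n_female_individuals + 1`` as a sentinel when even the largest
    attainable count keeps the probability above ``p_max`` (cannot happen
    for the carrier model, whose probability reaches 0 at F + 1).
    """
    if not 0 < p_max <= 1:
        raise DomainError("p_max must be in (0, 1]")
    F = n_female_individuals
    for n in range(0, F + 2):
        if carrier_probability(n, n_male_chr, F, model=model) <= p_max:
            return n
    return F + 1


def build_nonclinical_dbsnp(
    panel: ReferencePanel, min_allele_count: int = 12
) -> ReferencePanel:
    """Drop clinically pathogenic records, then records below the safe
    allele-count cutoff, leaving a subtraction panel of common neutral
    variants.

    The cutoff is parameterized as a copy count (default 12, the smallest
    count whose all-female-carrier probability is <= 1% in the reference
    population of 525 male + 2x567 female X chromosomes) rather than the
    rounded frequency it corresponds to.
    """
    r = panel.records
    for col in ("clin_sig", "allele_count"):
        if col not in r.columns:
            raise ConfigurationError(f"panel lacks required column {col!r}")
    mask = ~r["clin_sig"].isin(PATHOGENIC) & (r["allele_count"] >= min_allele_count)
    return panel.subset(mask)


def male_only_subset(
    panel: ReferencePanel,
    genotype_audit=None,
    max_ambiguous_frac: float = 0.0,
) -> ReferencePanel:
    """Retain records observed in at least one male.

    When a ``genotype_audit`` (a GenotypeAudit of the panel's male genotype
    values) is supplied, the build is refused outright if its ambiguous
    fraction exceeds ``max_ambiguous_frac`` — a release whose male X calls
    violate haploidy cannot be trusted as an automatic filter.
    """
    if genotype_audit is not None and genotype_audit.frac_ambiguous > max_ambiguous_frac:
        raise PanelIntegrityError(
            f"male genotypes fail the ploidy audit "
            f"({genotype_audit.frac_ambiguous:.1%} ambiguous > "
            f"{max_ambiguous_frac:.1%} allowed); refusing to build a male-only panel"
        )
    r = panel.records
    if "male_carrier_count" in r.columns:
        mask = r["male_carrier_count"] >= 1
    elif "female_only" in r.columns:
        mask = ~r["female_only"].astype(bool)
    else:
        raise ConfigurationError(
            "panel lacks a sex partition (male_carrier_count or female_only column)"
        )
    return panel.subset(mask)


def evs_male_subset(
    panel: ReferencePanel, par_mask: Sequence[tuple[int, int]] = ()
) -> ReferencePanel:
    """Retain records annotated as hemizygous in males, excluding any in the
    pseudoautosomal mask (0-based half-open intervals)."""
    r = panel.records
    if "hemizygous_annotated" not in r.columns:
        raise ConfigurationError("panel lacks hemizygous_annotated column")
    mask = r["hemizygous_annotated"].astype(bool)
    for lo, hi in par_mask:
        mask &= ~((r["pos"] - 1 >= lo) & (r["pos"] - 1 < hi))
    return panel.subset(mask)


def subtract_panel(
    callset: SampleCallSet,
    panel: ReferencePanel,
    stage_name: str,
    rescued: Iterable[VariantKey] = (),
) -> tuple[SampleCallSet, list[LedgerEntry]]:
    """Reject every call whose key appears in the panel, except rescued keys."""
    rescued = set(rescued)
    panel_keys = panel.key_set
    kept = []
    entries: list[LedgerEntry] = []
    for call in callset:
        if call.key in panel_keys and call.key not in rescued:
            entries.append(LedgerEntry(callset.sample_id, *call.key, stage_name, REJECT, stage_name))
        else:
            kept.append(call)
            entries.append(LedgerEntry(callset.sample_id, *call.key, stage_name, RETAIN, "-"))
    out = SampleCallSet(callset.sample_id, kept, sex=callset.sex, batch=callset.batch)
    return out, entries
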