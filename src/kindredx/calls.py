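"""Sample-level haploid variant calls and genotype-level statistics.

The male X chromosome (outside the pseudoautosomal regions) is hemizygous, so
a valid call carries 0 or 1 copies of the alternate allele.  ``genotype`` is
nevertheless stored as a real number so that raw datasets with ambiguous
copy-number values (2, 3, 0.05, 3.95, ...) can be audited rather than
silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import DuplicateVariantError, UndefinedStatisticError

#: (chrom, pos, ref, alt) — the exact-match key used by every filter stage.
VariantKey = tuple[str, int, str, str]

FUNC_CLASSES = (
    "nonsense",
    "frameshift",
    "splicing",
    "missense",
    "synonymous",
    "intronic",
    "other",
)

#: Classes that qualify a variant as potentially protein-damaging.
NONSYN_OR_SPLICING = frozenset({"nonsense", "frameshift", "splicing", "missense"})


@dataclass(frozen=True, slots=True)
class VariantCall:
    """One sample-level call on the haploid X chromosome.

    ``alt_fwd``/``alt_rev`` are the alternate-allele read counts split by
    sequencing strand; they feed the strand-representation prefilter.  They
    are optional because external call sets may lack strand information.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: float = 1.0
    depth: int | None = None
    alt_fwd: int | None = None
    alt_rev: int | None = None
    func_class: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")
        if self.alt_fwd is not None and self.alt_fwd < 0:
            raise ValueError("alt_fwd must be >= 0")
        if self.alt_rev is not None and self.alt_rev < 0:
            raise ValueError("alt_rev must be >= 0")
        if (
            self.depth is not None
            and self.alt_fwd is not None
            and self.alt_rev is not None
            and self.depth < self.alt_fwd + self.alt_rev
        ):
            raise ValueError(
                f"depth {self.depth} < alt_fwd+alt_rev "
                f"{self.alt_fwd + self.alt_rev} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_valid_haploid(self) -> bool:
        return self.genotype in (0.0, 1.0)

    def with_func_class(self, func_class: str) -> "VariantCall":
        return replace(self, func_class=func_class)


@dataclass
class SampleCallSet:
    """An ordered, deduplicated collection of calls for one male sample."""

    sample_id: str
    calls: list[VariantCall]
    sex: str = "male"
    batch: str = ""
    _key_index: dict[VariantKey, VariantCall] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=lambda c: c.key)
        index: dict[VariantKey, VariantCall] = {}
        for call in self.calls:
            if call.key in index:
                raise DuplicateVariantError(
                    f"duplicate variant key {call.key} in sample {self.sample_id}"
                )
            index[call.key] = call
        self._key_index = index

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._key_index

    @property
    def key_set(self) -> frozenset[VariantKey]:
        return frozenset(self._key_index)

    def get(self, key: VariantKey) -> VariantCall | None:
        return self._key_index.get(key)

    def positions(self) -> np.ndarray:
        return np.array([c.pos for c in self.calls], dtype=np.int64)

    def calls_at(self, pos: int) -> list[VariantCall]:
        return [c for c in self.calls if c.pos == pos]

    def subset(self, keys: Iterable[VariantKey]) -> "SampleCallSet":
        wanted = set(keys)
        return SampleCallSet(
            sample_id=self.sample_id,
            calls=[c for c in self.calls if c.key in wanted],
            sex=self.sex,
            batch=self.batch,
        )


@dataclass(frozen=True)
class GenotypeAudit:
    """Composition of non-zero genotype values in a call collection.

    ``frac_ambiguous`` covers every value outside {1, 2}, including all
    non-integer values — the pathology observed in the public 1000 Genomes
    male X-chromosome release.
    """

    n_nonzero: int
    frac_one: float
    frac_two: float
    frac_ambiguous: float


def audit_genotype_ploidy(
    genotypes: Iterable[float], expected_ploidy: int = 1
) -> GenotypeAudit:
    """Classify non-zero genotype values into {1, 2, ambiguous} fractions.

    Classification is ploidy-agnostic; ``expected_ploidy`` records the
    caller's interpretation (1 for a hemizygous male X) but does not change
    the counting.
    """
    if expected_ploidy not in (1, 2):
        raise ValueError("expected_ploidy must be 1 or 2")
    values = np.asarray(list(genotypes), dtype=float)
    nonzero = values[values != 0.0]
    if nonzero.size == 0:
        raise UndefinedStatisticError("all genotypes are zero; audit undefined")
    n = nonzero.size
    n_one = int(np.sum(nonzero == 1.0))
    n_two = int(np.sum(nonzero == 2.0))
    return GenotypeAudit(
        n_nonzero=n,
        frac_one=n_one / n,
        frac_two=n_two / n,
        frac_ambiguous=(n - n_one - n_two) / n,
    )


def genotype_concordance(
    callset: SampleCallSet, array_genotypes: Mapping[int, float] | Iterable[tuple[int, float]]
) -> float:
    """Fraction of positions shared with an array-genotype table whose
    genotypes agree.

    ``array_genotypes`` maps position -> genotype (e.g. a two-column TSV from
    an orthogonal genotyping array).  Overlap is on position; the callset's
    genotype at a position is the summed alt copy-number of its calls there.
    """
    if not isinstance(array_genotypes, Mapping):
        array_genotypes = dict(array_genotypes)
    call_gt: dict[int, float] = {}
    for call in callset:
        call_gt[call.pos] = call_gt.get(call.pos, 0.0) + call.genotype
    overlap = [p for p in array_genotypes if p in call_gt]
    if not overlap:
        raise UndefinedStatisticError(
            f"no positions overlap between sample {callset.sample_id} and the array table"
        )
    agree = sum(1 for p in overlap if call_gt[p] == array_genotypes[p])
    return agree / len(overlap)
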