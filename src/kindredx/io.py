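"""VCF, TSV and BED input/output for sample call sets and filter products.

The strand-split alternate-allele depths live in two configurable FORMAT
fields (default ``ADF``/``ADR``, each ``Number=1`` holding the alt-only
forward/reverse read count); a two-column sidecar TSV of
``pos<TAB>alt_fwd<TAB>alt_rev`` is accepted as a fallback for call sets whose
VCFs lack the fields.  The functional class is read from a configurable INFO
key (default ``FUNC``), defaulting to ``other`` when absent.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

# the strand-count dialect uses alt-only ADF/ADR (Number=1); htslib warns
# about the reserved Number=R definition, which is deliberate here
pysam.set_verbosity(0)

from .calls import FUNC_CLASSES, SampleCallSet, VariantCall
from .cohort import REJECT, FilterLedger
from .errors import SampleNotFoundError, VcfParseError

DEFAULT_STRAND_FIELDS = ("ADF", "ADR")
DEFAULT_FUNC_KEY = "FUNC"


def read_sample_vcf(
    path: str | Path,
    sample_id: str,
    strand_fields: tuple[str, str] = DEFAULT_STRAND_FIELDS,
    func_info_key: str = DEFAULT_FUNC_KEY,
    strand_sidecar: str | Path | None = None,
    batch: str = "",
) -> SampleCallSet:
    """Read one sample's haploid X calls from a VCF.

    Multi-allelic records are split into biallelic calls; the genotype of
    each split call is the copy-number of that alternate allele in GT.
    Calls with zero copies are dropped.
    """
    sidecar: dict[int, tuple[int, int]] = {}
    if strand_sidecar is not None:
        df = pd.read_csv(strand_sidecar, sep="\t", header=None, names=["pos", "alt_fwd", "alt_rev"])
        sidecar = {int(r.pos): (int(r.alt_fwd), int(r.alt_rev)) for r in df.itertuples()}

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    with vf:
        if sample_id not in list(vf.header.samples):
            raise SampleNotFoundError(f"sample {sample_id!r} not present in {path}")
        calls: list[VariantCall] = []
        for rec in vf:
            try:
                calls.extend(
                    _calls_from_record(rec, sample_id, strand_fields, func_info_key, sidecar)
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise VcfParseError(
                    f"malformed record at {rec.chrom}:{rec.pos} in {path}: {exc}"
                ) from exc
    return SampleCallSet(sample_id=sample_id, calls=calls, batch=batch)


def _calls_from_record(
    rec: "pysam.VariantRecord",
    sample_id: str,
    strand_fields: tuple[str, str],
    func_info_key: str,
    sidecar: Mapping[int, tuple[int, int]],
) -> list[VariantCall]:
    sample = rec.samples[sample_id]
    gt = sample.get("GT") or ()
    alleles = [a for a in gt if a is not None]
    dp = sample.get("DP")
    fwd = sample.get(strand_fields[0])
    rev = sample.get(strand_fields[1])
    if isinstance(fwd, tuple):
        fwd = fwd[0]
    if isinstance(rev, tuple):
        rev = rev[0]
    if fwd is None and rec.pos in sidecar:
        fwd, rev = sidecar[rec.pos]
    func = rec.info.get(func_info_key)
    if isinstance(func, tuple):
        func = func[0]
    if func not in FUNC_CLASSES:
        func = "other"
    out = []
    for alt_index, alt in enumerate(rec.alts or (), start=1):
        copies = sum(1 for a in alleles if a == alt_index)
        if copies == 0:
            continue
        out.append(
            VariantCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                genotype=float(copies),
                depth=None if dp is None else int(dp),
                alt_fwd=None if fwd is None else int(fwd),
                alt_rev=None if rev is None else int(rev),
                func_class=func,
            )
        )
    return out


def _build_header(
    sample_id: str,
    chrom: str,
    contig_length: int,
    strand_fields: tuple[str, str],
    func_info_key: str,
    filter_reasons: Iterable[str] = (),
) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line(f"##contig=<ID={chrom},length={contig_length}>")
    h.add_meta(
        "INFO",
        items=[("ID", func_info_key), ("Number", "1"), ("Type", "String"), ("Description", "Functional class of the variant")],
    )
    h.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    h.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"), ("Description", "Read depth")])
    h.add_meta(
        "FORMAT",
        items=[("ID", strand_fields[0]), ("Number", "1"), ("Type", "Integer"), ("Description", "Alt-allele reads on forward strand")],
    )
    h.add_meta(
        "FORMAT",
        items=[("ID", strand_fields[1]), ("Number", "1"), ("Type", "Integer"), ("Description", "Alt-allele reads on reverse strand")],
    )
    for reason in sorted(set(filter_reasons)):
        h.add_meta("FILTER", items=[("ID", reason), ("Description", f"Rejected: {reason}")])
    h.add_sample(sample_id)
    return h


def write_sample_vcf(
    callset: SampleCallSet,
    path: str | Path,
    contig_length: int = 155_000_000,
    strand_fields: tuple[str, str] = DEFAULT_STRAND_FIELDS,
    func_info_key: str = DEFAULT_FUNC_KEY,
    rejected: Sequence[tuple[VariantCall, str]] = (),
) -> None:
    """Write a call set as an uncompressed VCF (one sample).

    ``rejected`` optionally carries (call, reason) pairs to emit with the
    reason in the FILTER column ("annotate mode") instead of dropping them.
    """
    chroms = {c.chrom for c in callset.calls} | {c.chrom for c, _ in rejected} or {"X"}
    chrom = sorted(chroms)[0]
    header = _build_header(
        callset.sample_id, chrom, contig_length, strand_fields, func_info_key,
        (reason for _, reason in rejected),
    )
    records: list[tuple[VariantCall, str | None]] = [(c, None) for c in callset.calls]
    records.extend((c, reason) for c, reason in rejected)
    records.sort(key=lambda item: item[0].key)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call, reason in records:
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt),
            )
            rec.info[func_info_key] = call.func_class
            rec.filter.add("PASS" if reason is None else reason)
            fmt = rec.samples[callset.sample_id]
            fmt["GT"] = (int(round(call.genotype)),)
            if call.depth is not None:
                fmt["DP"] = call.depth
            if call.alt_fwd is not None:
                fmt[strand_fields[0]] = call.alt_fwd
            if call.alt_rev is not None:
                fmt[strand_fields[1]] = call.alt_rev
            out.write(rec)


def write_outputs(
    callset: SampleCallSet,
    ledger: FilterLedger,
    out_dir: str | Path,
    contig_length: int = 155_000_000,
    annotate: bool = False,
) -> dict[str, Path]:
    """Emit the filtered VCF plus the tab-separated ledger for one sample.

    The retained records are those the ledger never rejects (or rejects but
    later rescues).  A round-trip read of the VCF reproduces the retained
    calls exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sample_entries = [e for e in ledger if e.sample_id == callset.sample_id]
    missing = callset.key_set - {e.key for e in sample_entries}
    if missing:
        raise ValueError(
            f"ledger does not cover {len(missing)} calls of sample {callset.sample_id}"
        )
    rejected_keys: dict = {}
    for e in sample_entries:
        if e.decision == REJECT:
            rejected_keys.setdefault(e.key, e.reason)
        elif e.decision == "rescue":
            rejected_keys.pop(e.key, None)
    retained = callset.subset(k for k in callset.key_set if k not in rejected_keys)
    rejected = (
        [(callset.get(k), reason) for k, reason in rejected_keys.items() if callset.get(k)]
        if annotate
        else []
    )
    vcf_path = out_dir / f"{callset.sample_id}.filtered.vcf"
    write_sample_vcf(retained, vcf_path, contig_length=contig_length, rejected=rejected)
    ledger_path = out_dir / f"{callset.sample_id}.ledger.tsv"
    FilterLedger(sample_entries).to_tsv(ledger_path)
    return {"vcf": vcf_path, "ledger": ledger_path}


def read_array_genotypes(path: str | Path) -> dict[int, float]:
    """Two-column TSV (pos, genotype) from an orthogonal genotyping array."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pos", "genotype"])
    return {int(r.pos): float(r.genotype) for r in df.itertuples()}


def read_bed_intervals(path: str | Path) -> list[tuple[int, int]]:
    """BED intervals (0-based half-open) on a single chromosome."""
    out: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            out.append((int(parts[1]), int(parts[2])))
    return sorted(out)


def write_bed_intervals(
    intervals: Iterable[tuple[int, int]], path: str | Path, chrom: str = "X",
    names: Iterable[str] | None = None,
) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, (start, end) in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
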