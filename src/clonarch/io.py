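"""Readers and writers for the on-disk tables of the pipeline.

All tabular formats are tab-separated text with a header line.  Coordinates
are 1-based and closed (SEG convention) for both mutations and segments;
chromosome names are normalized by stripping a leading ``chr`` so that mixed
dialects from different cohorts can be combined.

Parsers never silently drop rows: every malformed row is collected in the
``rejects`` list of the returned :class:`ParseResult` together with its line
number and the reason, so ``rows in == records out + rejects``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = frozenset("ACGT")

__all__ = [
    "MutationRecord",
    "SegmentRecord",
    "SamplePurity",
    "ArmDefinition",
    "ClinicalRecord",
    "ReferenceSignatureMatrix",
    "ParseResult",
    "FormatError",
    "read_mutations",
    "write_mutations",
    "read_segments",
    "write_segments",
    "read_purity",
    "write_purity",
    "read_arms",
    "write_arms",
    "read_clinical",
    "write_clinical",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_reference_signatures",
    "write_reference_signatures",
    "mutations_to_frame",
    "segments_to_frame",
]


class FormatError(ValueError):
    """A file-level format problem (missing column, wrong shape)."""


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV in one sample, with tumor/normal read support."""

    sample_id: str
    gene: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    tumor_alt_count: int
    tumor_depth: int
    normal_alt_count: int
    normal_depth: int
    effect: str  # "silent" | "non_silent"
    context_5p: str | None = None
    context_3p: str | None = None

    def validate(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(
                f"alleles must be single bases, got {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele equals alt_allele")
        if not (0 <= self.tumor_alt_count <= self.tumor_depth):
            raise ValueError(
                f"tumor_alt_count {self.tumor_alt_count} > tumor_depth {self.tumor_depth}"
            )
        if self.tumor_depth < 1 or self.normal_depth < 1:
            raise ValueError("depths must be positive")
        if not (0 <= self.normal_alt_count <= self.normal_depth):
            raise ValueError(
                f"normal_alt_count {self.normal_alt_count} > normal_depth {self.normal_depth}"
            )
        if self.effect not in ("silent", "non_silent"):
            raise ValueError(f"effect must be silent/non_silent, got {self.effect!r}")
        for b in (self.context_5p, self.context_3p):
            if b is not None and b not in BASES:
                raise ValueError(f"context base {b!r} not in ACGT")

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt_count / self.tumor_depth

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt_count / self.normal_depth


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment (1-based closed coordinates)."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    total_copy_number: int
    segment_ccf: float | None = None  # fraction of tumor cells carrying the alteration

    def validate(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.total_copy_number < 0:
            raise ValueError("total_copy_number must be >= 0")
        if self.segment_ccf is not None and not (0.0 <= self.segment_ccf <= 1.0):
            raise ValueError(f"segment_ccf {self.segment_ccf} outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SamplePurity:
    sample_id: str
    purity: float
    ploidy: float

    def validate(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside (0,1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")


@dataclass(frozen=True)
class ArmDefinition:
    arm_id: str
    chromosome: str
    start: int
    end: int

    def validate(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"arm {self.arm_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    survival_time: float  # months
    event_observed: bool
    age: float
    sex: str
    t_stage: str  # T1..T4
    fuhrman_grade: str  # G1..G4

    def validate(self) -> None:
        if self.survival_time <= 0:
            raise ValueError("survival_time must be positive")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.t_stage not in ("T1", "T2", "T3", "T4"):
            raise ValueError(f"t_stage {self.t_stage!r} not in T1..T4")
        if self.fuhrman_grade not in ("G1", "G2", "G3", "G4"):
            raise ValueError(f"fuhrman_grade {self.fuhrman_grade!r} not in G1..G4")


class ReferenceSignatureMatrix:
    """A 96-channel reference signature catalog (COSMIC-style).

    ``frame`` is a DataFrame with the 96 context labels as index and one
    column per named signature; every column sums to 1.
    """

    def __init__(self, frame: pd.DataFrame):
        from .signatures import CONTEXT_CHANNELS  # local import: avoid cycle

        if list(frame.index) != list(CONTEXT_CHANNELS):
            if sorted(frame.index) == sorted(CONTEXT_CHANNELS):
                frame = frame.loc[list(CONTEXT_CHANNELS)]
            else:
                raise FormatError("reference matrix must have the 96 context channels as rows")
        vals = frame.to_numpy(dtype=float)
        if (vals < 0).any():
            raise FormatError("reference signatures must be nonnegative")
        sums = vals.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise FormatError("every reference signature column must sum to 1 (within 1e-6)")
        self.frame = frame

    @property
    def channels(self) -> list[str]:
        return list(self.frame.index)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class ParseResult:
    """Records that validated, plus per-row rejects (line number, reason)."""

    records: list
    rejects: list[tuple[int, str]]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "tumor_alt_count",
    "tumor_depth",
    "normal_alt_count",
    "normal_depth",
    "effect",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s): {', '.join(missing)}")


def read_mutations(path, reference_fasta_path=None) -> ParseResult:
    """Read a MAF-like mutation TSV into validated :class:`MutationRecord` s.

    If ``context_5p``/``context_3p`` columns are absent, flanking bases are
    fetched from ``reference_fasta_path`` (an indexed FASTA) on the reference
    strand as written; pyrimidine folding happens downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, MUTATION_COLUMNS, "mutation table")
    have_context = "context_5p" in df.columns and "context_3p" in df.columns
    fasta = None
    if not have_context:
        if reference_fasta_path is None:
            raise FormatError(
                "mutation table lacks context_5p/context_3p columns and no reference FASTA given"
            )
        from pyfaidx import Fasta

        fasta = Fasta(str(reference_fasta_path))

    records: list[MutationRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            d = row._asdict()
            chrom = _norm_chrom(d["chromosome"])
            if have_context:
                c5 = d.get("context_5p")
                c3 = d.get("context_3p")
                c5 = None if c5 in (None, "", ".") or c5 != c5 else str(c5).upper()
                c3 = None if c3 in (None, "", ".") or c3 != c3 else str(c3).upper()
            else:
                pos = int(d["position"])
                key = chrom if chrom in fasta else "chr" + chrom
                seq = fasta[key][pos - 2 : pos + 1].seq.upper()
                if len(seq) != 3:
                    raise ValueError("position too close to contig edge for context fetch")
                if seq[1] != str(d["ref_allele"]).upper():
                    raise ValueError(
                        f"reference base mismatch at {chrom}:{pos}: FASTA {seq[1]} vs {d['ref_allele']}"
                    )
                c5, c3 = seq[0], seq[2]
            rec = MutationRecord(
                sample_id=str(d["sample_id"]),
                gene=str(d["gene"]),
                chromosome=chrom,
                position=int(d["position"]),
                ref_allele=str(d["ref_allele"]).upper(),
                alt_allele=str(d["alt_allele"]).upper(),
                tumor_alt_count=int(d["tumor_alt_count"]),
                tumor_depth=int(d["tumor_depth"]),
                normal_alt_count=int(d["normal_alt_count"]),
                normal_depth=int(d["normal_depth"]),
                effect=str(d["effect"]),
                context_5p=c5,
                context_3p=c3,
            )
            rec.validate()
            records.append(rec)
        except (ValueError, KeyError) as exc:
            rejects.append((i, str(exc)))
    return ParseResult(records, rejects)


def mutations_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(MutationRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    df = mutations_to_frame(records)
    with open(path, "w") as fh:
        fh.write("# somatic SNVs; coordinates 1-based\n")
        df.to_csv(fh, sep="\t", index=False)


SEGMENT_COLUMNS = ["sample_id", "chromosome", "start", "end", "total_copy_number", "segment_ccf"]


def read_segments(path) -> ParseResult:
    """Read a SEG-style TSV; coordinates 1-based closed, sorted on return.

    Overlapping segments within one (sample, chromosome) raise a validation
    error naming the offending pair.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, SEGMENT_COLUMNS, "segment table")
    records: list[SegmentRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            ccf = d["segment_ccf"]
            ccf = None if ccf in (None, "", ".", "NA") or ccf != ccf else float(ccf)
            rec = SegmentRecord(
                sample_id=str(d["sample_id"]),
                chromosome=_norm_chrom(d["chromosome"]),
                start=int(d["start"]),
                end=int(d["end"]),
                total_copy_number=int(d["total_copy_number"]),
                segment_ccf=ccf,
            )
            rec.validate()
            records.append(rec)
        except ValueError as exc:
            rejects.append((i, str(exc)))
    records.sort(key=lambda r: (r.sample_id, r.chromosome, r.start))
    prev = None
    for rec in records:
        if (
            prev is not None
            and rec.sample_id == prev.sample_id
            and rec.chromosome == prev.chromosome
            and rec.start <= prev.end
        ):
            raise FormatError(
                f"overlapping segments in sample {rec.sample_id} chr{rec.chromosome}: "
                f"[{prev.start},{prev.end}] and [{rec.start},{rec.end}]"
            )
        prev = rec
    return ParseResult(records, rejects)


def segments_to_frame(records: Iterable[SegmentRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(SegmentRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)


def write_segments(records: Iterable[SegmentRecord], path) -> None:
    df = segments_to_frame(records)
    with open(path, "w") as fh:
        fh.write("# copy-number segments; coordinates 1-based closed\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_purity(path) -> list[SamplePurity]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    _require_columns(df, ["sample_id", "purity", "ploidy"], "purity table")
    out = []
    for row in df.itertuples(index=False):
        rec = SamplePurity(str(row.sample_id), float(row.purity), float(row.ploidy))
        rec.validate()
        out.append(rec)
    return out


def write_purity(records: Iterable[SamplePurity], path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.purity, r.ploidy) for r in records],
        columns=["sample_id", "purity", "ploidy"],
    ).to_csv(path, sep="\t", index=False)


def read_arms(path) -> list[ArmDefinition]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    _require_columns(df, ["arm_id", "chromosome", "start", "end"], "arm table")
    out = []
    for row in df.itertuples(index=False):
        rec = ArmDefinition(str(row.arm_id), _norm_chrom(row.chromosome), int(row.start), int(row.end))
        rec.validate()
        out.append(rec)
    # arms within a chromosome must not overlap
    by_chrom: dict[str, list[ArmDefinition]] = {}
    for a in out:
        by_chrom.setdefault(a.chromosome, []).append(a)
    for chrom, arms in by_chrom.items():
        arms = sorted(arms, key=lambda a: a.start)
        for a, b in zip(arms, arms[1:]):
            if b.start <= a.end:
                raise FormatError(f"arms {a.arm_id} and {b.arm_id} overlap on chr{chrom}")
    return out


def write_arms(records: Iterable[ArmDefinition], path) -> None:
    pd.DataFrame(
        [(r.arm_id, r.chromosome, r.start, r.end) for r in records],
        columns=["arm_id", "chromosome", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    _require_columns(
        df,
        ["sample_id", "survival_time", "event_observed", "age", "sex", "t_stage", "fuhrman_grade"],
        "clinical table",
    )
    out = []
    for row in df.itertuples(index=False):
        rec = ClinicalRecord(
            sample_id=str(row.sample_id),
            survival_time=float(row.survival_time),
            event_observed=bool(int(row.event_observed)),
            age=float(row.age),
            sex=str(row.sex),
            t_stage=str(row.t_stage),
            fuhrman_grade=str(row.fuhrman_grade),
        )
        rec.validate()
        out.append(rec)
    return out


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    pd.DataFrame(
        [
            (r.sample_id, r.survival_time, int(r.event_observed), r.age, r.sex, r.t_stage, r.fuhrman_grade)
            for r in records
        ],
        columns=["sample_id", "survival_time", "event_observed", "age", "sex", "t_stage", "fuhrman_grade"],
    ).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Genes x samples expression matrix; first column holds gene names."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", float_precision="round_trip")
    if df.shape[1] == 0:
        raise FormatError("expression matrix has no sample columns")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name, description, member genes per line.

    Duplicate members are de-duplicated (order preserved); empty sets are
    skipped with a warning; duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"GMT line {lineno}: expected name<TAB>description<TAB>genes...")
            name = parts[0]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if name in sets:
                raise FormatError(f"GMT: duplicate set name {name!r}")
            if not genes:
                warnings.warn(f"GMT set {name!r} has no genes; skipped")
                continue
            sets[name] = genes
    return sets


def write_gene_sets(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_reference_signatures(path) -> ReferenceSignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", float_precision="round_trip")
    return ReferenceSignatureMatrix(df.astype(float))


def write_reference_signatures(ref: ReferenceSignatureMatrix, path) -> None:
    ref.frame.to_csv(path, sep="\t", index_label="context")
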