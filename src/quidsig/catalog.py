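"""Genomic data model and file readers.

Coordinate conventions used throughout the package:

* mutations are 1-based inclusive positions (VCF convention);
* regions are 0-based half-open intervals (BED convention).

Every function that crosses the two conventions documents the conversion at
the call site.  Chromosome names are normalised by stripping a leading
``chr`` prefix so that mixed hg19 dialects interoperate.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase, N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix; leaves other names untouched."""
    return name[3:] if name.lower().startswith("chr") else name


class MutationRecord(NamedTuple):
    """A single somatic single-base substitution.

    ``pos`` is the 1-based position of the substituted base; ``ref`` and
    ``alt`` are single bases on the reference strand with ``alt != ref``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str


_CATALOG_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]


@dataclass
class MutationCatalog:
    """An ordered collection of SBS records for one or more samples.

    Duplicate (sample, chrom, pos, alt) tuples are collapsed to a single
    record on construction.  ``provenance`` records the source and the counts
    of rows filtered on the way in (indels, non-SNV alleles, malformed rows,
    reference mismatches).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        if list(df.columns) != _CATALOG_COLUMNS:
            df = df.loc[:, _CATALOG_COLUMNS]
        df = df.astype(
            {"sample_id": str, "chrom": str, "pos": np.int64, "ref": str, "alt": str}
        )
        df["chrom"] = df["chrom"].map(normalize_chrom)
        n_before = len(df)
        df = df.drop_duplicates(subset=["sample_id", "chrom", "pos", "alt"], keep="first")
        self.provenance.setdefault("n_duplicates_collapsed", n_before - len(df))
        bad = ~(df["ref"].isin(VALID_BASES) & df["alt"].isin(VALID_BASES))
        bad |= df["ref"] == df["alt"]
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} records are not valid single-base substitutions"
            )
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[MutationRecord], provenance: dict | None = None
    ) -> "MutationCatalog":
        df = pd.DataFrame(list(records), columns=_CATALOG_COLUMNS)
        return cls(df, dict(provenance or {}))

    @property
    def records(self) -> Iterator[MutationRecord]:
        for row in self.df.itertuples(index=False):
            yield MutationRecord(*row)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, sample_ids: Iterable[str]) -> "MutationCatalog":
        wanted = set(sample_ids)
        return MutationCatalog(
            self.df[self.df["sample_id"].isin(wanted)].copy(), dict(self.provenance)
        )

    def validate_against(self, genome: "ReferenceGenome") -> "MutationCatalog":
        """Drop records whose ref base disagrees with the genome.

        Mismatching records are rejected outright (never reverse-complement
        rescued: a silent strand flip would corrupt context classes).  The
        rejection count is recorded in provenance.
        """
        keep = np.ones(len(self.df), dtype=bool)
        for i, rec in enumerate(self.df.itertuples(index=False)):
            try:
                base = genome.base(rec.chrom, rec.pos)
            except (KeyError, IndexError):
                keep[i] = False
                continue
            keep[i] = base == rec.ref
        n_rejected = int((~keep).sum())
        prov = dict(self.provenance)
        prov["n_ref_mismatch_rejected"] = n_rejected
        if n_rejected:
            warnings.warn(
                f"{n_rejected} records rejected: ref base disagrees with genome"
            )
        return MutationCatalog(self.df[keep].copy(), prov)

    def merge(self, other: "MutationCatalog") -> "MutationCatalog":
        return MutationCatalog(
            pd.concat([self.df, other.df], ignore_index=True),
            {"merged": [self.provenance, other.provenance]},
        )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df, {"source": str(path)})


class ReferenceGenome:
    """In-memory reference with random access by (chrom, start, end).

    Sequences are stored and returned uppercase.  1-based inclusive queries
    outside [1, length] raise ``IndexError``.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seq = {normalize_chrom(c): s.upper() for c, s in sequences.items()}
        if not self._seq:
            raise ValueError("reference genome has no sequences")

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seq)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seq.items()}

    def sequence(self, chrom: str) -> str:
        return self._seq[normalize_chrom(chrom)]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        seq = self.sequence(chrom)
        if start < 1 or end > len(seq) or end < start:
            raise IndexError(
                f"query {chrom}:{start}-{end} outside [1, {len(seq)}]"
            )
        return seq[start - 1 : end]  # 1-based inclusive -> python slice

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def trinucleotide(self, chrom: str, pos: int) -> str:
        """The 3-mer centred on the 1-based position ``pos``."""
        return self.fetch(chrom, pos - 1, pos + 1)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seq.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class RegionSet:
    """A set of 0-based half-open genomic intervals, sorted and merged.

    ``intervals`` maps chromosome -> (n, 2) int array of [start, end) rows.
    Overlapping or bookended input intervals are merged on construction.
    """

    intervals: dict[str, np.ndarray]
    label: str = ""

    def __post_init__(self) -> None:
        merged = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError("interval with end <= start")
            merged[normalize_chrom(chrom)] = merge_intervals(arr)
        self.intervals = merged

    @classmethod
    def from_list(
        cls, rows: Iterable[tuple[str, int, int]], label: str = ""
    ) -> "RegionSet":
        by_chrom: dict[str, list] = {}
        for chrom, start, end in rows:
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: np.array(v) for c, v in by_chrom.items()}, label)

    @property
    def total_bp(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values())
        )

    @property
    def n_intervals(self) -> int:
        return int(sum(len(arr) for arr in self.intervals.values()))

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position (converted to 0-based internally)."""
        arr = self.intervals.get(normalize_chrom(chrom))
        if arr is None or len(arr) == 0:
            return False
        p0 = pos - 1  # 1-based mutation -> 0-based region coordinate
        i = np.searchsorted(arr[:, 0], p0, side="right") - 1
        return i >= 0 and p0 < arr[i, 1]

    def contains_many(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorised membership for an array of 1-based positions."""
        arr = self.intervals.get(normalize_chrom(chrom))
        pos = np.asarray(pos, dtype=np.int64)
        if arr is None or len(arr) == 0:
            return np.zeros(len(pos), dtype=bool)
        p0 = pos - 1
        i = np.searchsorted(arr[:, 0], p0, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = p0[ok] < arr[i[ok], 1]
        return out

    def subtract(self, other: "RegionSet") -> "RegionSet":
        """Remove every position of ``other`` from this set."""
        out = {}
        for chrom, arr in self.intervals.items():
            cut = other.intervals.get(chrom)
            if cut is None or len(cut) == 0:
                out[chrom] = arr.copy()
                continue
            pieces = []
            for start, end in arr:
                s = start
                for cs, ce in cut:
                    if ce <= s or cs >= end:
                        continue
                    if cs > s:
                        pieces.append((s, cs))
                    s = max(s, ce)
                    if s >= end:
                        break
                if s < end:
                    pieces.append((s, end))
            out[chrom] = (
                np.array(pieces, dtype=np.int64).reshape(-1, 2)
                if pieces
                else np.empty((0, 2), dtype=np.int64)
            )
        res = RegionSet.__new__(RegionSet)
        res.intervals = out
        res.label = self.label
        return res

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.intervals.items():
                for start, end in arr:
                    fh.write(f"{chrom}\t{start}\t{end}\n")

    def mask(self, length: int, chrom: str) -> np.ndarray:
        """Boolean per-position (0-based) membership mask for one chromosome."""
        out = np.zeros(length, dtype=bool)
        for start, end in self.intervals.get(normalize_chrom(chrom), []):
            out[max(0, start) : min(length, end)] = True
        return out


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping or bookended [start, end) rows; returns sorted rows."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr[np.argsort(arr[:, 0])]
    merged = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.array(merged, dtype=np.int64)


# ---------------------------------------------------------------------------
# readers


def read_vcf(path, sample_id: str) -> MutationCatalog:
    """Read biallelic SNVs from a VCF 4.x file into a catalog.

    Multi-allelic rows are split into one record per SNV allele; non-SNV
    ALT alleles (indels, symbolic, spanning deletions) are skipped and
    counted in provenance.
    """
    from cyvcf2 import VCF

    records = []
    n_non_snv = 0
    vcf = VCF(str(path))
    for var in vcf:
        ref = var.REF.upper()
        for alt in var.ALT:
            alt = alt.upper()
            if len(ref) == 1 and len(alt) == 1 and ref in VALID_BASES and alt in VALID_BASES:
                records.append(
                    MutationRecord(sample_id, var.CHROM, var.POS, ref, alt)
                )
            else:
                n_non_snv += 1
    vcf.close()
    return MutationCatalog.from_records(
        records, {"source": str(path), "n_non_snv_skipped": n_non_snv}
    )


_MAF_REQUIRED = {
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
}


def read_maf(path) -> MutationCatalog:
    """Read a TCGA-style tab-delimited MAF; keeps Variant_Type == SNP rows.

    The tumor sample barcode is used as the sample identifier.  MAF
    positions are already 1-based for SNPs, so no coordinate shift applies.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = _MAF_REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"MAF is missing required column(s): {sorted(missing)}")
    snp = df[df["Variant_Type"].str.upper() == "SNP"]
    out = pd.DataFrame(
        {
            "sample_id": snp["Tumor_Sample_Barcode"],
            "chrom": snp["Chromosome"],
            "pos": snp["Start_Position"].astype(np.int64),
            "ref": snp["Reference_Allele"].str.upper(),
            "alt": snp["Tumor_Seq_Allele2"].str.upper(),
        }
    )
    return MutationCatalog(
        out,
        {"source": str(path), "n_non_snp_skipped": int(len(df) - len(snp))},
    )


def read_fasta(path) -> ReferenceGenome:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return ReferenceGenome(seqs)


def read_bed(path, label: str = "") -> RegionSet:
    """Read a BED3+ file (0-based half-open).  Rows with end <= start are
    skipped with a warning."""
    rows = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                n_bad += 1
                continue
            rows.append((chrom, start, end))
    if not rows and n_bad == 0:
        raise ValueError(f"empty BED file: {path}")
    if n_bad:
        warnings.warn(f"skipped {n_bad} BED rows with end <= start")
    return RegionSet.from_list(rows, label or str(path))


def read_cohorts(path) -> pd.DataFrame:
    """Read a sample -> cohort table (TSV with columns sample_id, cohort,
    plus optional covariates); returns a DataFrame indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("cohort table needs at least sample_id and cohort columns")
    df = df.rename(columns={df.columns[0]: "sample_id", df.columns[1]: "cohort"})
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in cohort table")
    return df.set_index("sample_id")


def check_cohorts(catalog: MutationCatalog, cohorts: pd.DataFrame) -> None:
    """Every catalog sample must carry exactly one cohort label."""
    missing = set(catalog.samples) - set(cohorts.index)
    if missing:
        raise ValueError(f"samples without cohort label: {sorted(missing)}")
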