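"""96-class trinucleotide context classification and context-pattern statistics.

Substitutions are collapsed onto the pyrimidine strand (COSMIC convention):
a record whose reference base is a purine is reverse-complemented, together
with its flanking context, before classification.  The resulting 96 classes
are the six pyrimidine substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 4 x 4 possible 5' and 3' flanking bases.

Class order is fixed — substitution-major, then 5' base, then 3' base, both
alphabetical — so that matrices serialise identically across runs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from quidsig.catalog import (
    VALID_BASES,
    MutationCatalog,
    MutationRecord,
    ReferenceGenome,
    revcomp,
)

SUBSTITUTION_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = ["A", "C", "G", "T"]

#: the fixed 96-class order, e.g. "C>A:ACA", ..., "T>G:TTT"
CONTEXT_CLASSES = [
    f"{sub}:{five}{sub[0]}{three}"
    for sub in SUBSTITUTION_TYPES
    for five in BASES
    for three in BASES
]

_CLASS_INDEX = {c: i for i, c in enumerate(CONTEXT_CLASSES)}

#: the 16 C>T context classes in fixed order (used by the enrichment module)
CT_CLASSES = [c for c in CONTEXT_CLASSES if c.startswith("C>T")]


def class_label(sub: str, five: str, three: str) -> str:
    return f"{sub}:{five}{sub[0]}{three}"


def classify_trinucleotide(tri: str, ref: str, alt: str) -> str | None:
    """Classify a substitution given its reference-strand trinucleotide.

    ``tri`` is the 3-mer centred on the substituted base, read on the
    reference strand; ``ref``/``alt`` are the reference-strand alleles.
    Returns the pyrimidine-strand class label, or None when any of the three
    context bases is not A/C/G/T (unclassifiable).
    """
    tri = tri.upper()
    if len(tri) != 3 or any(b not in VALID_BASES for b in tri):
        return None
    if tri[1] != ref:
        raise ValueError(f"trinucleotide {tri} does not match ref allele {ref}")
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        tri = revcomp(tri)
        ref = revcomp(ref)
        alt = revcomp(alt)
    return class_label(f"{ref}>{alt}", tri[0], tri[2])


def classify_substitution(
    record: MutationRecord, genome: ReferenceGenome
) -> str | None:
    """Pyrimidine-strand context class of a record, or None if unclassifiable
    (flanking N, or position at a chromosome edge)."""
    try:
        tri = genome.trinucleotide(record.chrom, record.pos)
    except (KeyError, IndexError):
        return None
    if tri[1] != record.ref:
        raise ValueError(
            f"record {record} ref disagrees with genome base {tri[1]}"
        )
    return classify_trinucleotide(tri, record.ref, record.alt)


def build_context_matrix(
    catalog: MutationCatalog, genome: ReferenceGenome
) -> pd.DataFrame:
    """Samples x 96 count matrix of classified substitutions.

    Row sums equal the number of classifiable SBSs per sample; the count of
    unclassifiable records is stored per sample in ``df.attrs``.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    samples = catalog.samples
    counts = pd.DataFrame(
        0, index=pd.Index(samples, name="sample"), columns=CONTEXT_CLASSES, dtype=np.int64
    )
    unclassifiable = {s: 0 for s in samples}
    for rec in catalog.records:
        label = classify_substitution(rec, genome)
        if label is None:
            unclassifiable[rec.sample_id] += 1
        else:
            counts.at[rec.sample_id, label] += 1
    counts.attrs["unclassifiable"] = unclassifiable
    zero_rows = counts.index[counts.sum(axis=1) == 0]
    if len(zero_rows):
        warnings.warn(f"samples with no classifiable records: {list(zero_rows)}")
    return counts


def collapse_six(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse the 96 context classes to the six substitution types."""
    out = pd.DataFrame(index=matrix.index, columns=SUBSTITUTION_TYPES, dtype=np.int64)
    for sub in SUBSTITUTION_TYPES:
        cols = [c for c in CONTEXT_CLASSES if c.startswith(sub)]
        out[sub] = matrix[cols].sum(axis=1)
    return out


def ct_context_table_16(matrix: pd.DataFrame) -> pd.DataFrame:
    """The 16 C>T context columns of a context matrix, in fixed order."""
    return matrix[CT_CLASSES].copy()


def ct_pattern_proportions(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample share of C>T mutations from the GCG and TCN contexts.

    p_GCG = count(C>T:GCG) / all C>T; p_TCN = sum of the four C>T:TCx
    classes / all C>T.  Samples with zero C>T mutations get NaN and are
    flagged in the ``defined`` column.
    """
    ct = matrix[CT_CLASSES]
    total = ct.sum(axis=1).astype(float)
    tcn_cols = [class_label("C>T", "T", b) for b in BASES]
    with np.errstate(invalid="ignore", divide="ignore"):
        p_gcg = matrix[class_label("C>T", "G", "G")] / total
        p_tcn = ct[tcn_cols].sum(axis=1) / total
    out = pd.DataFrame(
        {"p_GCG": p_gcg, "p_TCN": p_tcn, "n_CT": total.astype(int), "defined": total > 0}
    )
    out.loc[~out["defined"], ["p_GCG", "p_TCN"]] = np.nan
    return out


def strand_preference_test(catalog: MutationCatalog) -> dict:
    """Reference-strand preference of C>T mutations.

    Counts records written as C>T (pyrimidine reference) versus G>A (purine
    reference, the same event on the opposite strand) before strand
    collapsing, and tests the split against 0.5 with a two-sided exact
    binomial test.  Under strand symmetry the two counts are exchangeable.
    """
    df = catalog.df
    is_ct = (df["ref"] == "C") & (df["alt"] == "T")
    is_ga = (df["ref"] == "G") & (df["alt"] == "A")
    n_c = int(is_ct.sum())
    n_g = int(is_ga.sum())
    if n_c + n_g == 0:
        raise ValueError("no C>T / G>A records in catalog")
    p = stats.binomtest(n_c, n_c + n_g, 0.5, alternative="two-sided").pvalue
    return {"n_pyrimidine_ref": n_c, "n_purine_ref": n_g, "p_value": float(p)}


#: the 32 pyrimidine-strand trinucleotide contexts (C-centred, then T-centred)
PYRIMIDINE_CONTEXTS = [
    f"{five}{centre}{three}" for centre in "CT" for five in BASES for three in BASES
]


def _context_lut() -> np.ndarray:
    """Map 64 trinucleotide codes (16a+4b+c over ACGT) to pyrimidine-strand
    context indices."""
    idx = {c: i for i, c in enumerate(PYRIMIDINE_CONTEXTS)}
    lut = np.zeros(64, dtype=np.int64)
    for a, ba in enumerate(BASES):
        for b, bb in enumerate(BASES):
            for c, bc in enumerate(BASES):
                tri = ba + bb + bc
                if bb in "GA":
                    tri = revcomp(tri)
                lut[16 * a + 4 * b + c] = idx[tri]
    return lut


_CTX_LUT = _context_lut()
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def context_site_counts(genome: ReferenceGenome, regions) -> pd.Series:
    """Number of positions inside ``regions`` whose pyrimidine-strand
    trinucleotide matches each of the 32 contexts.

    Used as context-aware denominators for per-class enrichment.  Positions
    at chromosome edges (no full trinucleotide) are not counted.
    """
    totals = np.zeros(32, dtype=np.int64)
    for chrom in genome.chromosomes:
        arr = regions.intervals.get(chrom)
        if arr is None or len(arr) == 0:
            continue
        seq = np.frombuffer(genome.sequence(chrom).encode(), dtype=np.uint8)
        valid = np.isin(seq, _BASE_BYTES)
        codes = np.searchsorted(_BASE_BYTES, seq).astype(np.int64)
        codes[~valid] = 0
        tri = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
        ctx = _CTX_LUT[tri]  # context of 0-based centre position i+1
        ok = valid[:-2] & valid[1:-1] & valid[2:]
        mask = regions.mask(len(seq), chrom)[1:-1] & ok
        totals += np.bincount(ctx[mask], minlength=32)
    return pd.Series(totals, index=PYRIMIDINE_CONTEXTS)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != CONTEXT_CLASSES:
        raise ValueError("matrix columns do not match the fixed 96-class order")
    return df
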