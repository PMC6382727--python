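"""CpG-island regional mutation-enrichment analysis.

For a set of islands, two disjoint window sets are built per island:

* **core** — the island extended by 50 nt on both sides;
* **flank** — the two 500-nt blocks lying 501-1000 nt outward from each
  island edge.

The 51-500 nt buffer between them belongs to neither set.  Cores are merged
first; flank blocks are clipped against every core and merged among
themselves, so no genomic position is counted twice.  Mutation rates are
compared between the pooled core and flank sets as

    fold = (n_core / core_bp) / (n_flank / flank_bp)

with a two-sided Fisher's exact test on the 2 x 2 table
[[n_core, core_bp - n_core], [n_flank, flank_bp - n_flank]], whose
denominators are total nucleotide positions.  The same test is applied per
mutation class (the six substitution types and the 16 C>T contexts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from quidsig.catalog import (
    MutationCatalog,
    MutationRecord,
    ReferenceGenome,
    RegionSet,
)
from quidsig.context import (
    CT_CLASSES,
    SUBSTITUTION_TYPES,
    classify_substitution,
    context_site_counts,
)


@dataclass
class WindowSet:
    """Paired, disjoint core/flank interval sets derived from islands."""

    core: RegionSet
    flank: RegionSet
    n_edge_clipped: int = 0

    @property
    def core_bp(self) -> int:
        return self.core.total_bp

    @property
    def flank_bp(self) -> int:
        return self.flank.total_bp


CORE_PAD = 50       # nt added to each island side to form the core window
FLANK_NEAR = 500    # flank starts 501 nt from the island edge (0-based offset 500)
FLANK_FAR = 1000    # ...and ends 1000 nt from it


def build_windows(islands: RegionSet, genome: ReferenceGenome) -> WindowSet:
    """Construct core and flank window sets from an island region set.

    All coordinates are 0-based half-open.  For an island [s, e): the core
    is [s-50, e+50); the flanks are [s-1000, s-500) and [e+500, e+1000),
    i.e. the 501st..1000th nt outward from each edge in 1-based language.
    Everything is clipped to the chromosome, and flank blocks are clipped
    against all (merged) cores.
    """
    lengths = genome.lengths
    n_clipped = 0
    core_rows = []
    flank_rows = []
    for chrom, arr in islands.intervals.items():
        L = lengths.get(chrom)
        if L is None:
            raise KeyError(f"island chromosome {chrom!r} absent from genome")
        for s, e in arr:
            cs, ce = s - CORE_PAD, e + CORE_PAD
            if cs < 0 or ce > L:
                n_clipped += 1
            core_rows.append((chrom, max(0, cs), min(L, ce)))
            for fs, fe in ((s - FLANK_FAR, s - FLANK_NEAR), (e + FLANK_NEAR, e + FLANK_FAR)):
                fs, fe = max(0, fs), min(L, fe)
                if fe > fs:
                    flank_rows.append((chrom, fs, fe))
    core = RegionSet.from_list(core_rows, label="core")
    flank = RegionSet.from_list(flank_rows, label="flank").subtract(core)
    return WindowSet(core=core, flank=flank, n_edge_clipped=n_clipped)


_ALL = "all"


def count_by_window(
    catalog: MutationCatalog, windows: WindowSet, genome: ReferenceGenome
) -> pd.DataFrame:
    """Tally catalog records into core/flank by position and mutation class.

    Returns a DataFrame indexed by class ("all", the 6 substitution types,
    and the 16 C>T context classes) with columns n_core and n_flank.
    Records outside both window sets are ignored; unclassifiable records
    count toward "all" but not toward any class row.
    """
    classes = [_ALL, *SUBSTITUTION_TYPES, *CT_CLASSES]
    counts = pd.DataFrame(0, index=pd.Index(classes, name="class"),
                          columns=["n_core", "n_flank"], dtype=np.int64)
    df = catalog.df
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        in_core = windows.core.contains_many(chrom, pos)
        in_flank = windows.flank.contains_many(chrom, pos)
        for where, mask in (("n_core", in_core), ("n_flank", in_flank)):
            if not mask.any():
                continue
            for rec_row in sub[mask].itertuples(index=False):
                label = classify_substitution(MutationRecord(*rec_row), genome)
                counts.loc[_ALL, where] += 1
                if label is not None:
                    sub_type = label.split(":")[0]
                    counts.loc[sub_type, where] += 1
                    if label in CT_CLASSES:
                        counts.loc[label, where] += 1
    return counts


def enrichment_test(
    n_core: int, n_flank: int, core_bp: int, flank_bp: int
) -> dict:
    """Rate-ratio fold change and two-sided Fisher exact p for one class.

    fold = (n_core/core_bp) / (n_flank/flank_bp); +inf (flagged) when
    n_flank is 0 and n_core > 0; NaN when both counts are 0.
    """
    if core_bp <= 0 or flank_bp <= 0:
        raise ValueError("window sizes must be positive")
    if n_core > core_bp or n_flank > flank_bp or n_core < 0 or n_flank < 0:
        raise ValueError("counts exceed window size or are negative")
    if n_flank == 0:
        fold = np.nan if n_core == 0 else np.inf
    else:
        fold = (n_core / core_bp) / (n_flank / flank_bp)
    table = [[n_core, core_bp - n_core], [n_flank, flank_bp - n_flank]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"fold": float(fold), "p_value": float(p)}


def _class_denominators(
    cls: str, windows: WindowSet, core_sites: pd.Series, flank_sites: pd.Series
) -> tuple[int, int]:
    """Context-aware (core, flank) denominators for one table row."""
    if cls == _ALL:
        return windows.core_bp, windows.flank_bp
    if cls in SUBSTITUTION_TYPES:
        centre = cls[0]  # C or T: all contexts with that central pyrimidine
        idx = [c for c in core_sites.index if c[1] == centre]
    else:
        idx = [cls.split(":")[1]]
    return int(core_sites[idx].sum()), int(flank_sites[idx].sum())


def per_class_enrichment(
    catalog: MutationCatalog,
    windows: WindowSet,
    genome: ReferenceGenome,
    fdr: bool = False,
    context_denominators: bool = False,
) -> pd.DataFrame:
    """Enrichment table over all classes: counts, rates, fold and Fisher p.

    Raw p-values are reported; pass ``fdr=True`` to add a Benjamini-
    Hochberg-adjusted column (off by default — the headline analysis uses
    uncorrected values).  With ``context_denominators=True`` the per-class
    denominators count only context-eligible positions (e.g. NCG-context
    sites for C>T:NCG), removing the composition confound of the 16-class
    test; the default uses total nucleotide positions for every row.
    """
    counts = count_by_window(catalog, windows, genome)
    if context_denominators:
        core_sites = context_site_counts(genome, windows.core)
        flank_sites = context_site_counts(genome, windows.flank)
    rows = []
    for cls, row in counts.iterrows():
        if context_denominators:
            core_bp, flank_bp = _class_denominators(
                cls, windows, core_sites, flank_sites
            )
        else:
            core_bp, flank_bp = windows.core_bp, windows.flank_bp
        res = enrichment_test(int(row["n_core"]), int(row["n_flank"]), core_bp, flank_bp)
        rows.append(
            {
                "class": cls,
                "n_core": int(row["n_core"]),
                "n_flank": int(row["n_flank"]),
                "core_bp": core_bp,
                "flank_bp": flank_bp,
                "fold": res["fold"],
                "p_value": res["p_value"],
            }
        )
    out = pd.DataFrame(rows).set_index("class")
    if fdr:
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


def per_sample_enrichment(
    catalog: MutationCatalog, windows: WindowSet, genome: ReferenceGenome
) -> pd.DataFrame:
    """All-class core-vs-flank fold and Fisher p for each sample separately
    (the pooled table is the headline mode)."""
    rows = []
    for sid in catalog.samples:
        counts = count_by_window(catalog.subset([sid]), windows, genome)
        n_core = int(counts.loc[_ALL, "n_core"])
        n_flank = int(counts.loc[_ALL, "n_flank"])
        res = enrichment_test(n_core, n_flank, windows.core_bp, windows.flank_bp)
        rows.append(
            {
                "sample": sid,
                "n_core": n_core,
                "n_flank": n_flank,
                "fold": res["fold"],
                "p_value": res["p_value"],
            }
        )
    return pd.DataFrame(rows).set_index("sample")
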