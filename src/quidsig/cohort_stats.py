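"""Cohort-level comparison statistics.

Mutation loads per sample (optionally restricted to an exome mask), one-way
ANOVA on loads across cohorts, and Fisher's exact test on gene
mutation-frequency 2 x 2 tables with a conditional-MLE odds ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from quidsig.catalog import MutationCatalog, RegionSet


def mutation_load(
    catalog: MutationCatalog, mask: RegionSet | None = None
) -> pd.Series:
    """Per-sample SBS counts, optionally counting only records inside a
    region mask (e.g. an exome BED for WGS catalogs)."""
    df = catalog.df
    if mask is not None:
        keep = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            keep[sub.index] = mask.contains_many(chrom, sub["pos"].to_numpy())
        df = df[keep]
        if df.empty:
            warnings.warn("mask intersects no catalog record")
    loads = df.groupby("sample_id").size()
    return loads.reindex(catalog.samples, fill_value=0).rename("load")


def anova_load(loads: pd.Series, cohorts: pd.DataFrame) -> dict:
    """Classic fixed-effects one-way ANOVA of per-sample loads across
    cohorts; returns the F statistic and p-value."""
    labels = cohorts.loc[loads.index, "cohort"]
    groups = [loads[labels == g].to_numpy(dtype=float) for g in labels.unique()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 cohorts with >= 2 samples each")
    f, p = stats.f_oneway(*groups)
    return {"F": float(f), "p_value": float(p)}


def gene_frequency_test(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Compare a gene's mutation frequency between two cohorts.

    ``k``/``n`` are mutated-sample counts and cohort sizes.  Two-sided
    Fisher's exact test on [[k1, n1-k1], [k2, n2-k2]]; the odds ratio is
    the conditional maximum-likelihood estimate.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("cohort size must be positive")
        if not 0 <= k <= n:
            raise ValueError("mutated count outside [0, cohort size]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    res = stats.contingency.odds_ratio(table, kind="conditional")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "freq1": k1 / n1,
        "freq2": k2 / n2,
        "odds_ratio": float(res.statistic),
        "p_value": float(p),
    }


def gene_mutation_table(
    catalog: MutationCatalog, genes: pd.DataFrame
) -> pd.DataFrame:
    """Gene x sample binary indicator of >= 1 mutation in the gene body.

    ``genes`` is BED-like with columns gene, chrom, start, end (0-based
    half-open).  Functional-consequence annotation is out of scope, so every
    SBS inside the interval counts; pre-filter the catalog to nonsynonymous
    records when frequencies of coding mutations are wanted.
    """
    samples = catalog.samples
    out = pd.DataFrame(0, index=genes["gene"], columns=samples, dtype=np.int8)
    df = catalog.df
    for row in genes.itertuples(index=False):
        hit = df[
            (df["chrom"] == str(row.chrom).removeprefix("chr"))
            & (df["pos"] > row.start)   # 1-based pos vs 0-based half-open
            & (df["pos"] <= row.end)
        ]
        for s in hit["sample_id"].unique():
            out.loc[row.gene, s] = 1
    return out
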