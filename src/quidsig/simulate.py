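"""Synthetic genomes, CpG-island annotations and signature-mixture catalogs.

The generator emulates the statistical structure of betel-quid-associated
(BQ-TC) and TCGA tongue-carcinoma cohorts so the whole analysis pipeline can
be exercised without any external download:

* a background sequence with CpG-suppressed dinucleotide composition and
  regularly spaced CpG islands of elevated CpG density.  The elevated
  density extends through a +/-1 kb neighbourhood around each island
  (emulating CpG-island shores), so the core-vs-flank enrichment comparison
  is not confounded by composition differences between the two window sets
  and the fitted fold change estimates the configured rate multiplier;
* three synthetic mutational processes: an NCG>NTG-concentrated process
  (CpG-deamination-like, "Sig-1-like"), a TCN-concentrated process with a
  C>G majority (APOBEC-like, "Sig-13-like"), and a flat background process
  ("Sig-5-like");
* catalogs drawn class-first: each mutation first draws a 96-class from the
  sample's signature mixture, then a genomic site uniformly among the
  positions whose pyrimidine-strand trinucleotide matches the class
  context, with island-core positions (as built by
  :func:`quidsig.enrichment.build_windows`) weighted by the island rate
  multiplier.  The catalog's expected 96-class distribution therefore
  equals the mixture exactly, which keeps recovery tests sharp.

Two packaged profiles describe the emulated cohorts; their numeric values
are chosen so that the simulated cohorts reproduce the reported summary
statistics of the corresponding study cohorts (mutation loads, signature
proportions, island enrichment and the C>T share of island mutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from quidsig.catalog import (
    MutationCatalog,
    ReferenceGenome,
    RegionSet,
)
from quidsig.context import BASES, CONTEXT_CLASSES
from quidsig.enrichment import build_windows

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3
_COMP = np.array([_T, _G, _C, _A])

#: the 32 pyrimidine-strand trinucleotide contexts, C-centred then T-centred
CONTEXTS_32 = [f"{f}{c}{t}" for c in "CT" for f in BASES for t in BASES]
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_32)}

#: context id of each of the 96 classes
CLASS_CONTEXT = np.array(
    [_CONTEXT_INDEX[label.split(":")[1]] for label in CONTEXT_CLASSES]
)
#: pyrimidine-strand alt base code of each class
CLASS_ALT = np.array(["ACGT".index(label[2]) for label in CONTEXT_CLASSES])


def _trinuc_lut() -> tuple[np.ndarray, np.ndarray]:
    """Map each of the 64 trinucleotide codes (16*a+4*b+c) to its
    pyrimidine-strand context id, plus a flag for purine-centred codes."""
    lut = np.full(64, -1, dtype=np.int64)
    flipped = np.zeros(64, dtype=bool)
    for a in range(4):
        for b in range(4):
            for c in range(4):
                code = 16 * a + 4 * b + c
                if b in (_C, _T):
                    five, cen, three = a, b, c
                else:  # purine centre: reverse complement
                    five, cen, three = _COMP[c], _COMP[b], _COMP[a]
                    flipped[code] = True
                tri = "ACGT"[five] + "ACGT"[cen] + "ACGT"[three]
                lut[code] = _CONTEXT_INDEX[tri]
    return lut, flipped


_TRI_LUT, _TRI_FLIPPED = _trinuc_lut()


# ---------------------------------------------------------------------------
# synthetic signatures


#: 5' base preference of the NCG>NTG process.  The emulated cohort's
#: hallmark is a G preceding the mutated C (GCG>GTG), with TCG the rarest
#: variant, so the NCG mass is split unevenly across the four 5' contexts.
SIG1_FIVE_PRIME = {"A": 0.20, "C": 0.20, "G": 0.50, "T": 0.10}


def sig1_like(ncg_weight: float = 0.39) -> pd.Series:
    """NCG>NTG-concentrated process: ``ncg_weight`` of the mass on the four
    C>T:NCG classes (split by :data:`SIG1_FIVE_PRIME`, GCG-dominant), the
    remainder uniform over the other 92 classes."""
    v = np.full(96, (1.0 - ncg_weight) / 92)
    for i, label in enumerate(CONTEXT_CLASSES):
        tri = label.split(":")[1]
        if label.startswith("C>T") and tri[1] == "C" and tri[2] == "G":
            v[i] = ncg_weight * SIG1_FIVE_PRIME[tri[0]]
    return pd.Series(v, index=CONTEXT_CLASSES, name="sig1_like")


def sig13_like(cg_fraction: float = 0.75) -> pd.Series:
    """TCN-concentrated APOBEC-like process: C>G (majority) and C>T
    mutations at the four TCx contexts."""
    v = np.zeros(96)
    for i, label in enumerate(CONTEXT_CLASSES):
        sub, tri = label.split(":")
        if tri[0] == "T" and tri[1] == "C":
            if sub == "C>G":
                v[i] = cg_fraction / 4
            elif sub == "C>T":
                v[i] = (1.0 - cg_fraction) / 4
    return pd.Series(v, index=CONTEXT_CLASSES, name="sig13_like")


def sig5_like() -> pd.Series:
    """Flat background process: uniform over all 96 classes."""
    return pd.Series(np.full(96, 1 / 96), index=CONTEXT_CLASSES, name="sig5_like")


def generating_signatures(ncg_weight: float = 0.39, cg_fraction: float = 0.75) -> pd.DataFrame:
    """The three generating signatures as a 96 x 3 matrix."""
    return pd.concat(
        [sig1_like(ncg_weight), sig13_like(cg_fraction), sig5_like()], axis=1
    )


def synthetic_reference_panel(n: int = 30, seed: int = 0) -> pd.DataFrame:
    """A synthetic 96 x n reference panel for matching tests.

    The first three columns are the generating processes; the rest are
    random sparse signatures (Dirichlet with a handful of concentrated
    classes).  Purely synthetic — no published signature values are used.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    gen = generating_signatures()
    for i in range(n):
        name = f"REF{i + 1:02d}"
        if i < gen.shape[1]:
            cols[name] = gen.iloc[:, i].to_numpy()
        else:
            alpha = np.full(96, 0.05)
            alpha[rng.choice(96, size=rng.integers(3, 8), replace=False)] = 3.0
            cols[name] = rng.dirichlet(alpha)
    return pd.DataFrame(cols, index=CONTEXT_CLASSES)


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class GenomeSpec:
    """Geometry and composition of a simulated reference chromosome."""

    length: int = 10_000_000
    n_islands: int = 100
    island_length: int = 1_000
    cpg_rate_island: float = 0.03      # CpG plant probability per position
    cpg_rate_background: float = 0.01
    neighborhood_pad: int = 1_000      # shore width sharing island composition
    chrom: str = "sim1"


@dataclass(frozen=True)
class CohortProfile:
    """Statistical description of an emulated cohort.

    ``mixture_means`` are the cohort-mean signature weights in the order
    (sig1_like, sig13_like, sig5_like); per-sample weights are drawn from a
    Dirichlet with concentration ``mixture_concentration * means``.
    Mutation loads are negative-binomial with the given mean and shape.
    """

    name: str
    n_samples: int
    mixture_means: tuple[float, float, float]
    mixture_concentration: float = 30.0
    wgs_load_mean: float = 8056.0
    wgs_load_shape: float = 10.0
    exome_load_mean: float = 70.0
    exome_load_shape: float = 4.0
    island_multiplier: float = 2.05
    sig1_ncg_weight: float = 0.39
    sig13_cg_fraction: float = 0.75
    genome: GenomeSpec = field(default_factory=GenomeSpec)

    @property
    def signatures(self) -> pd.DataFrame:
        return generating_signatures(self.sig1_ncg_weight, self.sig13_cg_fraction)

    def load_mean(self, scale: str) -> tuple[float, float]:
        if scale == "wgs":
            return self.wgs_load_mean, self.wgs_load_shape
        if scale == "exome":
            return self.exome_load_mean, self.exome_load_shape
        raise ValueError("scale must be 'wgs' or 'exome'")


#: packaged cohort emulation profiles
PROFILES: dict[str, CohortProfile] = {
    # 15 betel-quid tongue carcinomas: ~8e3 SBS per genome / ~70 per exome,
    # dominant NCG>NTG process (mean weight 0.53, spread ~0.35-0.72), minor
    # APOBEC-like (0.09) and flat (0.38) processes, island rate multiplier
    # 2.05.  The NCG concentration of the dominant process and the island
    # CpG-density contrast are calibrated together so that C>T mutations
    # make up ~48% of the mutations in island core windows.
    "bq_tc": CohortProfile(
        name="bq_tc",
        n_samples=15,
        mixture_means=(0.53, 0.09, 0.38),
        island_multiplier=2.05,
    ),
    # 82 TCGA tongue carcinomas: exome loads, TCN-weighted mixture with the
    # APOBEC-like mean at 0.22, no island rate elevation.
    "tcga_tc": CohortProfile(
        name="tcga_tc",
        n_samples=82,
        mixture_means=(0.10, 0.22, 0.68),
        island_multiplier=1.0,
        genome=GenomeSpec(length=2_000_000, n_islands=20),
    ),
}


# ---------------------------------------------------------------------------
# genome simulation


def simulate_genome(
    spec: GenomeSpec, seed: int | np.random.SeedSequence | None = 0
) -> tuple[ReferenceGenome, RegionSet]:
    """Generate a reference chromosome and its CpG-island annotation.

    The sequence is i.i.d. uniform over A/C/G/T with accidental CpG
    dinucleotides rejected, after which CpGs are planted at the configured
    per-position rate — elevated inside each island and its +/- ``pad``
    neighbourhood, background elsewhere.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    L = spec.length
    gap = L // spec.n_islands
    need = spec.island_length + 2 * spec.neighborhood_pad
    if gap < need + 2:
        raise ValueError(
            f"genome geometry overflow: {spec.n_islands} islands of "
            f"{spec.island_length} nt (+{spec.neighborhood_pad} nt pad) "
            f"do not fit in {L} nt"
        )
    codes = rng.integers(0, 4, size=L, dtype=np.int8)
    # reject accidental CpG dinucleotides so planting controls the density
    for _ in range(64):
        cg = np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G))
        if len(cg) == 0:
            break
        codes[cg + 1] = rng.choice(np.array([_A, _C, _T], dtype=np.int8), size=len(cg))

    starts = np.arange(spec.n_islands) * gap + (gap - spec.island_length) // 2
    ends = starts + spec.island_length
    islands = RegionSet.from_list(
        [(spec.chrom, int(s), int(e)) for s, e in zip(starts, ends)], label="islands"
    )

    rate = np.full(L - 1, spec.cpg_rate_background)
    for s, e in zip(starts, ends):
        rate[max(0, s - spec.neighborhood_pad) : min(L - 1, e + spec.neighborhood_pad)] = (
            spec.cpg_rate_island
        )
    plant = np.flatnonzero(rng.random(L - 1) < rate)
    if len(plant):
        keep = np.ones(len(plant), dtype=bool)
        keep[1:] = np.diff(plant) > 1  # no overlapping plants
        plant = plant[keep]
        codes[plant] = _C
        codes[plant + 1] = _G
    seq = _BASE_ARR[codes].tobytes().decode("ascii")
    return ReferenceGenome({spec.chrom: seq}), islands


def cpg_density(genome: ReferenceGenome, regions: RegionSet, chrom: str) -> float:
    """CpG dinucleotides per position inside a region set."""
    seq = np.frombuffer(genome.sequence(chrom).encode(), dtype=np.uint8)
    codes = np.searchsorted(_BASE_ARR, seq)
    is_cg = (codes[:-1] == _C) & (codes[1:] == _G)
    mask = regions.mask(len(seq), chrom)[:-1]
    return float(is_cg[mask].sum() / mask.sum())


# ---------------------------------------------------------------------------
# catalog simulation


class SiteIndex:
    """Genomic positions of every pyrimidine-strand trinucleotide context,
    split into island-core and outside-core sets for weighted sampling."""

    def __init__(self, genome: ReferenceGenome, core: RegionSet, chrom: str):
        self.chrom = chrom
        seq = np.frombuffer(genome.sequence(chrom).encode(), dtype=np.uint8)
        codes = np.searchsorted(_BASE_ARR, seq).astype(np.int64)
        tri = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
        ctx = _TRI_LUT[tri]  # context id of position i+1 (0-based centre)
        core_mask = core.mask(len(seq), chrom)[1:-1]
        self.core_sites: list[np.ndarray] = []
        self.out_sites: list[np.ndarray] = []
        for c in range(32):
            hit = ctx == c
            centres = np.flatnonzero(hit) + 1  # 0-based centre position
            in_core = core_mask[centres - 1]
            # store 1-based positions
            self.core_sites.append(centres[in_core] + 1)
            self.out_sites.append(centres[~in_core] + 1)
        self._codes = codes

    def central_code(self, pos: np.ndarray) -> np.ndarray:
        return self._codes[np.asarray(pos) - 1]


def simulate_catalog(
    genome: ReferenceGenome,
    islands: RegionSet,
    mixture: np.ndarray | pd.Series,
    n_mut: int,
    island_multiplier: float = 1.0,
    seed: int | np.random.SeedSequence | None = 0,
    sample_id: str = "sim",
    site_index: SiteIndex | None = None,
) -> MutationCatalog:
    """Draw a catalog of exactly ``n_mut`` SBS records from a 96-class
    mixture.

    Each mutation draws its class from ``mixture``, then a site uniformly
    among positions matching the class context, with island-core positions
    (core = island +/- 50 nt) weighted by ``island_multiplier``.  Records
    are emitted on the reference strand; collisions at an already-mutated
    position are redrawn so the catalog has exactly ``n_mut`` records.  The
    drawn class of each record is stored in
    ``provenance["true_classes"]`` (aligned with catalog order).
    """
    p = np.asarray(mixture, dtype=float).ravel()
    if p.shape != (96,) or np.any(p < 0):
        raise ValueError("mixture must be a nonnegative 96-vector")
    p = p / p.sum()
    chrom = genome.chromosomes[0]
    if site_index is None:
        windows = build_windows(islands, genome)
        site_index = SiteIndex(genome, windows.core, chrom)
    for ci in np.flatnonzero(p > 0):
        ctx = CLASS_CONTEXT[ci]
        if len(site_index.core_sites[ctx]) + len(site_index.out_sites[ctx]) == 0:
            raise ValueError(
                f"no eligible site for class {CONTEXT_CLASSES[ci]} in the genome"
            )
    rng = np.random.default_rng(seed)
    M = float(island_multiplier)

    taken: dict[int, tuple[int, int]] = {}  # pos -> (class id, alt code)
    order: list[int] = []
    n_rounds = 0
    while len(taken) < n_mut:
        n_rounds += 1
        if n_rounds > 1000:
            raise RuntimeError(
                "site pool exhausted: n_mut too large for the genome's "
                "eligible sites under this mixture"
            )
        # draw exactly the deficit; a draw colliding with an occupied site
        # is discarded and redrawn (class and site) next round, so the
        # marginal class distribution stays equal to the mixture
        batch = n_mut - len(taken)
        classes = rng.choice(96, size=batch, p=p)
        for ci in np.unique(classes):
            idx = np.flatnonzero(classes == ci)
            ctx = CLASS_CONTEXT[ci]
            core = site_index.core_sites[ctx]
            out = site_index.out_sites[ctx]
            w_core = M * len(core)
            p_core = w_core / (w_core + len(out)) if (w_core + len(out)) > 0 else 0.0
            use_core = rng.random(len(idx)) < p_core
            pos = np.empty(len(idx), dtype=np.int64)
            if use_core.any():
                pos[use_core] = rng.choice(core, size=int(use_core.sum()))
            if (~use_core).any():
                pos[~use_core] = rng.choice(out, size=int((~use_core).sum()))
            for pp in pos:
                pp = int(pp)
                if pp in taken:
                    continue
                taken[pp] = (int(ci), int(CLASS_ALT[ci]))
                order.append(pp)

    rows = []
    true_classes = []
    for pp in order:
        ci, alt_pyr = taken[pp]
        ref_code = int(site_index.central_code(np.array([pp]))[0])
        if ref_code in (_C, _T):
            ref, alt = "ACGT"[ref_code], "ACGT"[alt_pyr]
        else:  # purine on the reference strand: emit the complement alleles
            ref, alt = "ACGT"[ref_code], "ACGT"[_COMP[alt_pyr]]
        rows.append((sample_id, chrom, pp, ref, alt))
        true_classes.append(CONTEXT_CLASSES[ci])
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt"])
    return MutationCatalog(
        df, {"true_classes": true_classes, "island_multiplier": M, "n_mut": n_mut}
    )


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortSimulation:
    """Everything produced by :func:`simulate_cohort`, including the drawn
    ground-truth parameters for recovery tests."""

    genome: ReferenceGenome
    islands: RegionSet
    catalog: MutationCatalog
    cohorts: pd.DataFrame
    truth: pd.DataFrame
    signatures: pd.DataFrame
    profile: CohortProfile


def simulate_cohort(
    profile: CohortProfile,
    seed: int | None = 0,
    scale: str = "wgs",
    n_mut_per_sample: int | None = None,
    genome: ReferenceGenome | None = None,
    islands: RegionSet | None = None,
) -> CohortSimulation:
    """Simulate a full cohort on a shared reference genome.

    Per-sample loads are negative-binomial at the profile's mean for the
    chosen ``scale`` (or fixed to ``n_mut_per_sample``); per-sample mixture
    weights are Dirichlet around the profile means.  The truth table records
    every drawn parameter.
    """
    root = np.random.SeedSequence(seed)
    ss_genome, ss_params, ss_catalogs = root.spawn(3)
    if genome is None or islands is None:
        genome, islands = simulate_genome(profile.genome, ss_genome)
    chrom = genome.chromosomes[0]
    windows = build_windows(islands, genome)
    site_index = SiteIndex(genome, windows.core, chrom)

    rng = np.random.default_rng(ss_params)
    n = profile.n_samples
    if n_mut_per_sample is not None:
        loads = np.full(n, int(n_mut_per_sample))
    else:
        mean, shape = profile.load_mean(scale)
        loads = rng.negative_binomial(shape, shape / (shape + mean), size=n)
        loads = np.maximum(loads, 10)  # avoid degenerate empty catalogs
    alpha = profile.mixture_concentration * np.asarray(profile.mixture_means)
    weights = rng.dirichlet(alpha, size=n)

    sigs = profile.signatures
    cat_seeds = ss_catalogs.spawn(n)
    catalogs = []
    sample_ids = [f"{profile.name}_{i + 1:02d}" for i in range(n)]
    for i, sid in enumerate(sample_ids):
        mixture = sigs.to_numpy() @ weights[i]
        catalogs.append(
            simulate_catalog(
                genome,
                islands,
                mixture,
                int(loads[i]),
                island_multiplier=profile.island_multiplier,
                seed=cat_seeds[i],
                sample_id=sid,
                site_index=site_index,
            )
        )
    combined = catalogs[0]
    for c in catalogs[1:]:
        combined = combined.merge(c)
    cohorts = pd.DataFrame(
        {"cohort": profile.name}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth = pd.DataFrame(
        {
            "load": loads,
            **{
                f"w_{name}": weights[:, j]
                for j, name in enumerate(sigs.columns)
            },
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CohortSimulation(
        genome=genome,
        islands=islands,
        catalog=combined,
        cohorts=cohorts,
        truth=truth,
        signatures=sigs,
        profile=profile,
    )
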