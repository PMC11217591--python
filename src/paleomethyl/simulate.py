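"""Synthetic paleomethylome cohorts with known truth.

Generates a miniature reference genome (CpG-island track, gene/exon table,
SNP mask), per-CpG truth methylomes with designated differentially
methylated genes, and UDG-treated aligned reads in which methylated
cytosines near fragment termini appear as C→T (G→A on reverse strands)
mismatches at probability m·d.  Laboratory profiles carry the technical
heterogeneity the analysis has to survive: per-lab damage rates spanning
roughly 1%–6% mean MS, coverages, fragment-length distributions and
library chemistry (single- vs double-stranded).

Unmethylated deaminated cytosines are never emitted: UDG excision is
modeled as "no event", which has the same likelihood for the scoring model.
Reads are emitted pre-aligned at their true positions — no sequencing
error, adapters, contamination or alignment noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reference as ref_mod
from .reference import catalog_cpgs, classify_context
from .scoring import (
    DEFAULT_DAMAGE_WINDOW,
    apply_depth_filter,
    count_site_evidence_table,
    eligible_inspections,
)

SUBSISTENCE = ("HG", "NF")
TISSUES = ("bone", "tooth")
SEXES = ("XX", "XY")
LIBRARIES = ("ss", "ds")

# island CpGs are hypomethylated; elsewhere methylation is high (60%-80%
# genome-wide is typical for vertebrate tissues)
ISLAND_BETA = (1.0, 9.0)
OPENSEA_BETA = (8.0, 2.0)

META_COLS = ["genome_id", "subsistence", "tissue", "sex", "laboratory", "library", "coverage"]


@dataclass
class LabProfile:
    """Technical profile of a producing laboratory."""

    lab_id: str
    damage_rate: float  # terminal deamination probability d per methylated C
    coverage: float  # mean depth of coverage targeted per genome
    library: str = "ds"
    frag_mean: float = 60.0  # lognormal fragment-length mean (bp)
    frag_sigma: float = 0.25  # lognormal sigma (log scale)
    min_frag: int = 35
    cgi_coverage: float = 1.0  # protocol-driven relative coverage of CGI regions

    def __post_init__(self):
        if not 0 < self.damage_rate < 1:
            raise ValueError("damage_rate must be in (0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.library not in LIBRARIES:
            raise ValueError(f"library must be one of {LIBRARIES}")
        if self.cgi_coverage <= 0:
            raise ValueError("cgi_coverage must be > 0")


@dataclass
class ReferenceBundle:
    """In-memory reference genome plus its annotation tracks."""

    sequences: dict[str, str]
    cgi: pd.DataFrame  # BED: chrom, start, end
    snp_mask: pd.DataFrame  # BED: chrom, start, end
    exon_table: pd.DataFrame  # gene_id, chrom, strand, exon_start, exon_end
    islands_declared: pd.DataFrame = None  # simulator's own island intervals

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def catalog(self, chromosomes: list[str] | None = None) -> pd.DataFrame:
        cat = catalog_cpgs(self.sequences, self.snp_mask, chromosomes)
        return classify_context(cat, self.cgi)


@dataclass
class TruthMethylome:
    """Per-CpG true methylation probabilities plus gene-level group effects."""

    sites: pd.DataFrame  # chrom, pos, context, m
    dmg_effects: pd.DataFrame  # gene_id, effect (additive shift for the NF group)
    effect_group: str = "NF"
    site_effect: pd.Series = None  # per-site delta aligned with `sites`

    def m_for(self, subsistence: str, chrx_factor: float = 1.0) -> pd.Series:
        """Effective per-site methylation for a genome of the given group."""
        m = self.sites["m"].copy()
        if subsistence == self.effect_group and self.site_effect is not None:
            m = m + self.site_effect
        if chrx_factor != 1.0:
            on_x = self.sites["chrom"].isin(["chrX", "X"]).to_numpy()
            m = m.where(~on_x, m * chrx_factor)
        return m.clip(0.0, 1.0)


@dataclass
class ReadSet:
    """Simulated aligned reads for one genome plus the truth ledger.

    ``reads``: read_id, chrom, start, end, is_reverse.
    ``ledger``: every eligible CpG inspection the molecules carry —
    read_id, chrom, pos (site key), base_pos, deaminated — so that a
    faithful scorer must reproduce exactly ``groupby(site).deaminated``.
    """

    genome_id: str
    library: str
    reads: pd.DataFrame
    ledger: pd.DataFrame

    def ledger_counts(self) -> pd.DataFrame:
        """Recount the ledger into per-site (n1, n0) — the scoring oracle."""
        g = self.ledger.groupby(["chrom", "pos"])["deaminated"]
        out = g.agg(n1="sum", total="count").reset_index()
        out["n0"] = out["total"] - out["n1"]
        return out[["chrom", "pos", "n1", "n0"]].sort_values(
            ["chrom", "pos"], ignore_index=True
        )


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def build_reference(
    n_chrom: int = 1,
    chrom_length: int = 200_000,
    n_islands: int = 5,
    island_length: int = 1_000,
    n_genes: int = 20,
    seed: int = 0,
    include_chrx: bool = False,
    snp_fraction: float = 0.01,
    gene_length: int = 2_000,
    island_cg_period: int = 8,
) -> ReferenceBundle:
    """Generate a reference bundle: sequence, CGI track, exon table, SNP mask.

    Autosomes are named chr1..chrN; with ``include_chrx`` an extra chrX of
    the same layout is appended.  Genes are evenly spaced two-exon models;
    the first ``n_islands`` genes carry a CpG island at their start
    (promoter CGIs).  Island spacing must leave room for the island plus
    its 2 kb shores and 2 kb shelves without overlapping the neighbours';
    a sizing error is raised otherwise.  Background sequence is uniform
    over ACGT (a CpG roughly every 16 bp); inside islands a CG is planted
    every ``island_cg_period`` bases, guaranteeing every island contains a
    CpG.
    """
    margin = ref_mod.SHORE_BP + ref_mod.SHELF_BP
    if n_genes > 0:
        anchor_spacing = chrom_length // (n_genes + 1)
        if n_islands > n_genes:
            raise ValueError("n_islands may not exceed n_genes (islands sit at gene promoters)")
    else:
        anchor_spacing = chrom_length // (n_islands + 1) if n_islands else chrom_length
    if n_islands > 0 and island_length + 2 * margin > anchor_spacing:
        raise ValueError(
            f"{n_islands} islands of {island_length} bp with {margin} bp flanks "
            f"do not fit in {chrom_length} bp"
        )
    if n_genes > 0 and gene_length > chrom_length // (n_genes + 1):
        raise ValueError(f"{n_genes} genes of {gene_length} bp do not fit in {chrom_length} bp")

    chroms = [f"chr{i + 1}" for i in range(n_chrom)] + (["chrX"] if include_chrx else [])
    sequences: dict[str, str] = {}
    cgi_rows, exon_rows, mask_rows, island_rows = [], [], [], []
    for ci, chrom in enumerate(chroms):
        rng = _rng(seed, 11, ci)
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_length)
        # genes: evenly spaced two-exon models, strand alternating; the first
        # n_islands genes carry a CpG island at their start (promoter CGIs,
        # the common situation in vertebrate genomes)
        gene_starts = []
        for gi in range(n_genes):
            gspacing = chrom_length // (n_genes + 1)
            gs = gspacing * (gi + 1) - gene_length // 2
            ge = gs + gene_length
            gene_starts.append(gs)
            gid = f"{chrom}_g{gi:03d}"
            strand = "+" if gi % 2 == 0 else "-"
            exon1 = (gs, gs + gene_length // 3)
            exon2 = (ge - gene_length // 2, ge)
            for es, ee in (exon1, exon2):
                exon_rows.append((gid, chrom, strand, es, ee))
        for i in range(n_islands):
            if gene_starts:
                s = gene_starts[i]
            else:
                s = anchor_spacing * (i + 1) - island_length // 2
            e = s + island_length
            for p in range(s, e - 1, island_cg_period):
                seq[p], seq[p + 1] = b"C", b"G"
            cgi_rows.append((chrom, s, e))
            island_rows.append((chrom, s, e))
        sequences[chrom] = seq.tobytes().decode()
    cgi = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    exon_table = pd.DataFrame(
        exon_rows, columns=["gene_id", "chrom", "strand", "exon_start", "exon_end"]
    )
    # SNP mask: a random fraction of CpG C-positions
    unmasked = catalog_cpgs(sequences)
    rng = _rng(seed, 13)
    k = int(round(snp_fraction * len(unmasked)))
    if k > 0:
        take = unmasked.iloc[np.sort(rng.choice(len(unmasked), size=k, replace=False))]
        mask_rows = [(c, p, p + 1) for c, p in zip(take["chrom"], take["pos"])]
    snp_mask = pd.DataFrame(mask_rows, columns=["chrom", "start", "end"])
    islands_declared = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return ReferenceBundle(sequences, cgi, snp_mask, exon_table, islands_declared)


def draw_truth_methylome(
    bundle: ReferenceBundle,
    island_mean: float = 0.1,
    opensea_mean: float = 0.8,
    dmg_fraction: float = 0.0,
    effect_size: float = 0.45,
    seed: int = 0,
    effect_group: str = "NF",
    sign_mode: str = "negative",
) -> TruthMethylome:
    """Draw per-CpG methylation probabilities and assign true DMG effects.

    Island CpGs are drawn from a Beta re-scaled to ``island_mean`` (default
    Beta(1,9)); everything else from one matching ``opensea_mean`` (default
    Beta(8,2)).  ``dmg_fraction`` of genes (rounded) receive an additive
    shift of magnitude ``effect_size`` applied to the NF group's CpGs within
    the gene span, clamped to [0,1].  ``sign_mode='negative'`` (default)
    makes every true DMG hypomethylated in farmers — shifts away from the
    high open-sea baseline keep their full magnitude instead of clamping at
    m = 1; ``'alternating'`` flips the sign gene by gene.
    """
    for v, name in ((island_mean, "island_mean"), (opensea_mean, "opensea_mean")):
        if not 0 < v < 1:
            raise ValueError(f"{name} must be in (0,1)")
    if not 0 <= dmg_fraction <= 1:
        raise ValueError("dmg_fraction must be in [0,1]")
    cat = bundle.catalog()
    rng = _rng(seed, 17)
    a_i, b_i = ISLAND_BETA
    a_o, b_o = OPENSEA_BETA
    # rescale the default Beta shapes to the requested means, keeping a+b
    a_i, b_i = island_mean * (a_i + b_i), (1 - island_mean) * (a_i + b_i)
    a_o, b_o = opensea_mean * (a_o + b_o), (1 - opensea_mean) * (a_o + b_o)
    is_island = (cat["context"] == "island").to_numpy()
    m = np.where(
        is_island,
        rng.beta(a_i, b_i, size=len(cat)),
        rng.beta(a_o, b_o, size=len(cat)),
    )
    sites = cat[["chrom", "pos", "context"]].copy()
    sites["m"] = m
    genes = ref_mod.derive_gene_intervals(bundle.exon_table)
    n_dmg = int(round(dmg_fraction * len(genes)))
    chosen = rng.choice(len(genes), size=n_dmg, replace=False) if n_dmg else np.array([], int)
    effects = []
    delta = np.zeros(len(sites))
    pos_by_chrom = {c: sub for c, sub in sites.groupby("chrom")}
    for j, gi in enumerate(np.sort(chosen)):
        g = genes[gi]
        if sign_mode == "negative":
            eff = -effect_size
        elif sign_mode == "alternating":
            eff = effect_size if j % 2 == 0 else -effect_size
        else:
            raise ValueError("sign_mode must be 'negative' or 'alternating'")
        effects.append((g.gene_id, eff))
        sub = pos_by_chrom.get(g.chrom)
        if sub is not None:
            inside = sub[(sub["pos"] >= g.start) & (sub["pos"] < g.end)]
            delta[inside.index] += eff
    dmg = pd.DataFrame(effects, columns=["gene_id", "effect"])
    return TruthMethylome(sites, dmg, effect_group, pd.Series(delta, index=sites.index))



def _uniform_in_intervals(rng, intervals: np.ndarray, n: int) -> np.ndarray:
    """n positions uniform over the union of half-open intervals (k x 2 array)."""
    lens = intervals[:, 1] - intervals[:, 0]
    cum = np.cumsum(lens)
    offs = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, offs, side="right")
    prev = np.concatenate([[0], cum[:-1]])
    return intervals[idx, 0] + (offs - prev[idx])


def _start_positions(rng, n_frags, lengths, L, islands, cgi_coverage, frag_mean):
    """Fragment starts, uniform or with a lab-specific CGI coverage bias.

    The bias multiplies start density over island intervals (extended one
    fragment length to the left so reverse-strand 5' ends are biased too),
    emulating protocol-driven over/under-representation of CpG-rich DNA.
    """
    if cgi_coverage == 1.0 or islands is None or not len(islands):
        return rng.integers(0, L - lengths + 1)
    ext = []
    for s0, e0 in islands:
        ext.append((max(0, s0 - int(frag_mean)), min(e0, L)))
    ext.sort()
    merged = []
    for s0, e0 in ext:
        if merged and s0 <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e0))
        else:
            merged.append((s0, e0))
    isl = np.array(merged, dtype=np.int64)
    comp = []
    prev = 0
    for s0, e0 in merged:
        if s0 > prev:
            comp.append((prev, s0))
        prev = e0
    if prev < L:
        comp.append((prev, L))
    comp = np.array(comp, dtype=np.int64)
    L_isl = int((isl[:, 1] - isl[:, 0]).sum())
    p_isl = cgi_coverage * L_isl / (cgi_coverage * L_isl + (L - L_isl))
    in_isl = rng.random(n_frags) < p_isl
    starts = np.empty(n_frags, dtype=np.int64)
    if in_isl.sum():
        starts[in_isl] = _uniform_in_intervals(rng, isl, int(in_isl.sum()))
    if (~in_isl).sum():
        starts[~in_isl] = _uniform_in_intervals(rng, comp, int((~in_isl).sum()))
    return np.minimum(starts, L - lengths)


def simulate_genome_reads(
    bundle: ReferenceBundle,
    truth: TruthMethylome,
    meta_row: pd.Series,
    lab: LabProfile,
    seed: int = 0,
    damage_window: int = DEFAULT_DAMAGE_WINDOW,
    chrx_female_factor: float = 1.0,
    chromosomes: list[str] | None = None,
) -> ReadSet:
    """Simulate one genome's UDG-treated aligned reads plus the truth ledger.

    Fragments are placed uniformly with discretized-lognormal lengths
    (floored at the 35 bp filter minimum) and Poisson-targeted coverage;
    male genomes get half coverage on chrX.  At every eligible terminal CpG
    inspection (5' window for ds libraries, both ends for ss) the base is
    deaminated with probability m·d; the ledger records each inspection.
    """
    gid = meta_row["genome_id"]
    d = lab.damage_rate
    sex = meta_row["sex"]
    subsistence = meta_row["subsistence"]
    m_eff = truth.m_for(subsistence, chrx_female_factor if sex == "XX" else 1.0)
    site_m = {
        chrom: (sub["pos"].to_numpy(), m_eff.to_numpy()[sub.index.to_numpy()])
        for chrom, sub in truth.sites.groupby("chrom")
    }
    mu = np.log(lab.frag_mean) - lab.frag_sigma**2 / 2
    reads_frames, ledger_frames = [], []
    rid_offset = 0
    chrom_iter = chromosomes if chromosomes is not None else list(bundle.sequences)
    for ci, chrom in enumerate(chrom_iter):
        L = bundle.chrom_lengths[chrom]
        cov = lab.coverage
        if chrom in ("chrX", "X") and sex == "XY":
            cov = cov / 2
        rng = _rng(seed, 23, ci)
        n_frags = rng.poisson(cov * L / lab.frag_mean)
        if n_frags == 0:
            continue
        lengths = np.maximum(
            np.round(rng.lognormal(mu, lab.frag_sigma, size=n_frags)).astype(np.int64),
            lab.min_frag,
        )
        lengths = np.minimum(lengths, L)
        chrom_islands = bundle.cgi[bundle.cgi["chrom"] == chrom][["start", "end"]].to_numpy()
        starts = _start_positions(rng, n_frags, lengths, L, chrom_islands,
                                  lab.cgi_coverage, lab.frag_mean)
        ends = starts + lengths
        is_rev = rng.random(n_frags) < 0.5
        cand = eligible_inspections(starts, ends, is_rev, lab.library, damage_window)
        pos_arr, m_arr = site_m.get(chrom, (np.array([], np.int64), np.array([])))
        if len(pos_arr):
            loc = np.clip(np.searchsorted(pos_arr, cand["site_pos"].to_numpy()), 0, len(pos_arr) - 1)
            hit = cand[pos_arr[loc] == cand["site_pos"].to_numpy()]
        else:
            hit = cand[:0]
        read_ids = np.arange(rid_offset, rid_offset + n_frags)
        reads_frames.append(
            pd.DataFrame(
                {
                    "read_id": read_ids,
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "is_reverse": is_rev,
                }
            )
        )
        if len(hit):
            site_idx = np.searchsorted(pos_arr, hit["site_pos"].to_numpy())
            m_site = m_arr[site_idx]
            dea = rng.random(len(hit)) < m_site * d
            ledger_frames.append(
                pd.DataFrame(
                    {
                        "read_id": read_ids[hit["read_idx"].to_numpy()],
                        "chrom": chrom,
                        "pos": hit["site_pos"].to_numpy(),
                        "base_pos": hit["base_pos"].to_numpy(),
                        "is_reverse": is_rev[hit["read_idx"].to_numpy()],
                        "deaminated": dea,
                    }
                )
            )
        rid_offset += n_frags
    reads = (
        pd.concat(reads_frames, ignore_index=True)
        if reads_frames
        else pd.DataFrame(columns=["read_id", "chrom", "start", "end", "is_reverse"])
    )
    ledger = (
        pd.concat(ledger_frames, ignore_index=True)
        if ledger_frames
        else pd.DataFrame(columns=["read_id", "chrom", "pos", "base_pos", "is_reverse", "deaminated"])
    )
    return ReadSet(gid, lab.library, reads, ledger)


def damage_substitutions(readset: ReadSet) -> pd.DataFrame:
    """Ledger rows turned into (read_id, base_pos, to_base) sequence edits."""
    dam = readset.ledger[readset.ledger["deaminated"]]
    to_base = np.where(dam["is_reverse"], "A", "T")
    return pd.DataFrame(
        {"read_id": dam["read_id"], "base_pos": dam["base_pos"], "to_base": to_base}
    )


def default_lab_profiles() -> dict[str, LabProfile]:
    """Six laboratories spanning the observed c.1%-6% mean-MS range.

    Coverages are chosen so that per-site informative depth under the 2 bp
    terminal window sits in the regime where the ≥4-read filter retains most
    sites, mirroring the real data's median-coverage genomes.
    """
    specs = [
        ("lab1", 0.012, 240.0, "ds", 0.6),
        ("lab2", 0.022, 300.0, "ds", 1.3),
        ("lab3", 0.035, 240.0, "ds", 0.8),
        ("lab4", 0.050, 180.0, "ds", 1.4),
        ("lab5", 0.065, 240.0, "ds", 0.6),
        ("lab6", 0.028, 150.0, "ss", 1.0),
    ]
    return {
        lid: LabProfile(lid, d, cov, lib, cgi_coverage=cgi)
        for lid, d, cov, lib, cgi in specs
    }


def default_cohort_meta(labs: dict[str, LabProfile] | None = None) -> pd.DataFrame:
    """The 34-genome cohort structure: 13 HG / 21 NF, 23 bone / 11 tooth,
    12 XX / 22 XY, six laboratories, four single-stranded libraries."""
    labs = labs or default_lab_profiles()
    # lab -> (n HG, n NF); three labs carry both subsistence types
    comp = {"lab1": (4, 4), "lab2": (3, 3), "lab3": (2, 6), "lab4": (4, 0),
            "lab5": (0, 5), "lab6": (0, 3)}
    rows = []
    i = 0
    for lab_id, (n_hg, n_nf) in comp.items():
        for subs, n in (("HG", n_hg), ("NF", n_nf)):
            for _ in range(n):
                sex = "XX" if i % 3 == 1 and sum(r[3] == "XX" for r in rows) < 12 else "XY"
                tissue = "tooth" if i % 3 == 2 and sum(r[2] == "tooth" for r in rows) < 11 else "bone"
                lp = labs[lab_id]
                rows.append(
                    (f"g{i:02d}", subs, tissue, sex, lab_id, lp.library, lp.coverage)
                )
                i += 1
    meta = pd.DataFrame(rows, columns=META_COLS)
    # top up the sex / tissue tallies deterministically to 12 XX and 11 tooth
    need_xx = 12 - (meta["sex"] == "XX").sum()
    if need_xx > 0:
        idx = meta.index[meta["sex"] == "XY"][:need_xx]
        meta.loc[idx, "sex"] = "XX"
    need_tooth = 11 - (meta["tissue"] == "tooth").sum()
    if need_tooth > 0:
        idx = meta.index[meta["tissue"] == "bone"][-need_tooth:]
        meta.loc[idx, "tissue"] = "tooth"
    return meta


def small_cohort_meta(
    n_genomes: int = 6,
    labs: dict[str, LabProfile] | None = None,
) -> tuple[pd.DataFrame, dict[str, LabProfile]]:
    """Scaled-down two-lab preset for tests: alternating HG/NF, balanced sexes."""
    if labs is None:
        labs = {
            "labA": LabProfile("labA", 0.02, 200.0, "ds"),
            "labB": LabProfile("labB", 0.05, 200.0, "ds"),
        }
    lab_ids = list(labs)
    rows = []
    for i in range(n_genomes):
        # block assignment keeps laboratory unaliased from the alternating
        # subsistence pattern and balanced in composition
        lab = lab_ids[(i // 2) % len(lab_ids)]
        rows.append(
            (
                f"g{i:02d}",
                "HG" if i % 2 == 0 else "NF",
                "bone" if i % 3 else "tooth",
                "XX" if i % 4 in (1, 2) else "XY",  # decoupled from subsistence
                lab,
                labs[lab].library,
                labs[lab].coverage,
            )
        )
    return pd.DataFrame(rows, columns=META_COLS), labs


def simulate_cohort(
    bundle: ReferenceBundle,
    truth: TruthMethylome,
    meta: pd.DataFrame,
    labs: dict[str, LabProfile],
    seed: int = 0,
    damage_window: int = DEFAULT_DAMAGE_WINDOW,
    chrx_female_factor: float = 1.0,
) -> dict[str, ReadSet]:
    """Simulate every genome in the metadata sheet; per-genome derived seeds."""
    out = {}
    for i, (_, row) in enumerate(meta.iterrows()):
        lab = labs[row["laboratory"]]
        out[row["genome_id"]] = simulate_genome_reads(
            bundle, truth, row, lab, seed=seed * 1000 + i,
            damage_window=damage_window, chrx_female_factor=chrx_female_factor,
        )
    return out


def simulate_cohort_counts(
    bundle: ReferenceBundle,
    truth: TruthMethylome,
    meta: pd.DataFrame,
    labs: dict[str, LabProfile],
    seed: int = 0,
    min_depth: int = 4,
    damage_window: int = DEFAULT_DAMAGE_WINDOW,
    chrx_female_factor: float = 1.0,
    chromosomes: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate and score one genome at a time, keeping only site counts.

    Memory-friendly path for larger cohorts: the read tables are dropped as
    soon as each genome's depth-filtered (chrom, pos, n1, n0, ms) counts are
    computed.
    """
    catalog = bundle.catalog(chromosomes)
    out = {}
    for i, (_, row) in enumerate(meta.iterrows()):
        lab = labs[row["laboratory"]]
        rs = simulate_genome_reads(
            bundle, truth, row, lab, seed=seed * 1000 + i,
            damage_window=damage_window, chrx_female_factor=chrx_female_factor,
            chromosomes=chromosomes,
        )
        dam = rs.ledger.loc[rs.ledger["deaminated"], ["read_id", "base_pos"]]
        cnt = count_site_evidence_table(rs.reads, dam, catalog, rs.library, damage_window)
        out[row["genome_id"]] = apply_depth_filter(cnt, min_depth)
        del rs
    return out


def make_external_dmg_table(
    truth: TruthMethylome,
    gene_ids: list[str],
    overlap_mode: str = "shared",
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """External modern differential-methylation table (gene, logFC, adj_p).

    ``shared`` mode draws logFC co-directional with the simulated NF−HG
    effects plus Gaussian noise; ``independent`` mode draws logFC with no
    relation to the truth.  adj_p is small for the table's own nominally
    significant genes and uniform otherwise (it is carried, not tested).
    """
    if overlap_mode not in ("shared", "independent"):
        raise ValueError("overlap_mode must be 'shared' or 'independent'")
    known = set(truth.dmg_effects["gene_id"])
    missing = known - set(gene_ids)
    if missing:
        raise ValueError(f"truth DMGs missing from gene id list: {sorted(missing)}")
    rng = _rng(seed, 31)
    eff = truth.dmg_effects.set_index("gene_id")["effect"]
    delta = np.array([eff.get(g, 0.0) for g in gene_ids])
    if overlap_mode == "shared":
        logfc = delta + rng.normal(0, noise_sd, size=len(gene_ids))
        if noise_sd == 0:
            logfc = delta.copy()
    else:
        logfc = rng.normal(0, 1.0, size=len(gene_ids))
    adj_p = np.where(np.abs(logfc) > 2 * max(noise_sd, 1e-9), rng.uniform(0, 0.05, len(gene_ids)),
                     rng.uniform(0, 1, len(gene_ids)))
    return pd.DataFrame({"gene": gene_ids, "logFC": logfc, "adj_p": adj_p})
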