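"""Gene-level differential-methylation statistics and cohort structure.

Two gene-level views of the normalized replicate datasets feed the tests:

* the *full* dataset keeps every CpG of every gene per replicate, so each
  genome contributes its read-level binary deamination evidence — used by
  the multistratum ANOVA models (subsistence + tissue + sex with an
  Error(individual) or Error(laboratory) stratum);
* the *gene-averaged* matrix collapses each gene x genome cell to the mean
  of its CpG MS values, averaged across replicates — one observation per
  genome, free of pseudoreplication, used by one-way ANOVA / Kruskal-Wallis
  screens, MDS clustering, the chrX sex analysis and co-directionality
  comparisons against external differential-methylation tables.

All multiple testing is Benjamini-Hochberg across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
FACTOR_ORDER = ("subsistence", "tissue", "sex")
FACTOR_LEVELS = {"subsistence": ("HG", "NF"), "tissue": ("bone", "tooth"), "sex": ("XX", "XY")}


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# gene datasets


def map_sites_to_genes(sites: pd.DataFrame, gene_tbl: pd.DataFrame, use_span: str = "gene") -> pd.DataFrame:
    """Assign catalog sites to genes by overlap with the gene (or exon) span.

    A site may belong to several overlapping genes.  Returns
    (chrom, pos, gene_id) rows.  ``use_span``: ``gene`` for the exon-bearing
    union interval (default), ``promoter`` for the 4 kb promoter.
    """
    lo_col, hi_col = ("start", "end") if use_span == "gene" else ("promoter_start", "promoter_end")
    out = []
    for chrom, sub in sites.groupby("chrom", observed=True):
        pos = np.sort(sub["pos"].unique())
        for _, g in gene_tbl[gene_tbl["chrom"] == chrom].iterrows():
            lo = np.searchsorted(pos, g[lo_col])
            hi = np.searchsorted(pos, g[hi_col])
            if hi > lo:
                out.append(pd.DataFrame({"chrom": chrom, "pos": pos[lo:hi], "gene_id": g["gene_id"]}))
    if not out:
        return pd.DataFrame(columns=["chrom", "pos", "gene_id"])
    return pd.concat(out, ignore_index=True)


def build_gene_datasets(
    replicates: list[dict[str, pd.DataFrame]],
    gene_tbl: pd.DataFrame,
    use_span: str = "gene",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build the full per-CpG gene dataset and the gene-averaged matrix.

    Returns ``(full, matrix, ncpg)``: ``full`` has one row per
    (replicate, gene, genome, site) with subsampled counts; ``matrix`` is
    genes x genomes mean MS averaged across the replicates in which the
    cell exists; ``ncpg`` the mean number of contributing CpGs per cell.
    """
    frames = []
    for r, rep in enumerate(replicates, start=1):
        for gid, counts in rep.items():
            c = counts.copy()
            c["genome_id"] = gid
            c["rep"] = r
            frames.append(c)
    allc = pd.concat(frames, ignore_index=True)
    sites = allc[["chrom", "pos"]].drop_duplicates()
    mapping = map_sites_to_genes(sites, gene_tbl, use_span)
    if not len(mapping):
        raise ValueError("no genes overlap any CpG site")
    full = allc.merge(mapping, on=["chrom", "pos"], how="inner")
    full["ms"] = full["n1"] / (full["n1"] + full["n0"])
    per_rep = (
        full.groupby(["gene_id", "genome_id", "rep"], sort=False, observed=True)
        .agg(ms=("ms", "mean"), n_cpg=("pos", "size"))
        .reset_index()
    )
    cell = per_rep.groupby(["gene_id", "genome_id"], observed=True).agg(
        ms=("ms", "mean"), n_cpg=("n_cpg", "mean")
    )
    matrix = cell["ms"].unstack("genome_id")
    ncpg = cell["n_cpg"].unstack("genome_id")
    matrix.columns.name = "genome"
    return full, matrix, ncpg


# ---------------------------------------------------------------------------
# multistratum linear models on the read-level binary response


def _seq_weighted_anova(y: np.ndarray, w: np.ndarray, terms: dict[str, np.ndarray]):
    """Sequential (Type I) weighted ANOVA of unit means, one df per term.

    Returns (per-term {name: (ss, estimable)}, rss, df_resid, total_ss).
    A term is inestimable when its column is aliased with earlier terms
    under the weight inner product.
    """
    n = len(y)
    basis = [np.ones(n)]
    ss_terms: dict[str, tuple[float, bool]] = {}
    ybar = np.average(y, weights=w)
    total = float(np.sum(w * (y - ybar) ** 2))
    n_est = 0
    for name, x in terms.items():
        e = x.astype(float).copy()
        for b in basis:
            denom = np.sum(w * b * b)
            if denom > 0:
                e -= (np.sum(w * e * b) / denom) * b
        norm = float(np.sum(w * e * e))
        if norm <= 1e-10 * max(1.0, float(np.sum(w * x * x))):
            ss_terms[name] = (0.0, False)
            continue
        ss = float(np.sum(w * y * e) ** 2 / norm)
        ss_terms[name] = (ss, True)
        basis.append(e)
        n_est += 1
    rss = total - sum(ss for ss, est in ss_terms.values() if est)
    df_resid = n - 1 - n_est
    return ss_terms, max(rss, 0.0), df_resid, total


def fit_stratified_model(
    gene_rows: pd.DataFrame,
    meta: pd.DataFrame,
    stratum: str = "individual",
    order: tuple[str, ...] = FACTOR_ORDER,
) -> dict[str, float]:
    """Multistratum ANOVA of read-level deamination for one gene.

    ``gene_rows`` carries (genome_id, n1, n0) — per-site rows or per-genome
    sums of the subsampled counts.  The binary response is aggregated to
    the stratum units (individuals or laboratories); fixed factors are
    tested sequentially in ``order`` against the between-unit residual mean
    square, weighted by read counts, which reproduces the between-unit
    stratum of the classical multistratum ANOVA for these designs.  Returns
    ``{factor: p}`` with NaN where a factor is inestimable.
    """
    if stratum not in ("individual", "laboratory"):
        raise ValueError("stratum must be 'individual' or 'laboratory'")
    per_g = gene_rows.groupby("genome_id", observed=True)[["n1", "n0"]].sum()
    m = meta.set_index("genome_id").loc[per_g.index]
    unit = per_g.index if stratum == "individual" else m["laboratory"]
    codes, _ = pd.factorize(np.asarray(unit))
    w_g = (per_g["n1"] + per_g["n0"]).to_numpy(float)
    y1_g = per_g["n1"].to_numpy(float)  # deaminated read counts
    n_units = codes.max() + 1
    w = np.bincount(codes, weights=w_g, minlength=n_units)
    out = {f: np.nan for f in order}
    keep = w > 0
    if keep.sum() < 2:
        return out
    y = np.bincount(codes, weights=y1_g, minlength=n_units)[keep] / w[keep]
    terms = {}
    for f in order:
        lv = FACTOR_LEVELS[f]
        x_g = (m[f] == lv[1]).to_numpy(float)
        terms[f] = np.bincount(codes, weights=w_g * x_g, minlength=n_units)[keep] / w[keep]
    w = w[keep]
    ss_terms, rss, df_resid, total = _seq_weighted_anova(y, w, terms)
    if df_resid < 1 or total <= 0 or rss <= 1e-300:
        return out
    for f, (ss, est) in ss_terms.items():
        if est:
            F = ss / (rss / df_resid)
            out[f] = float(stats.f.sf(F, 1, df_resid))
    return out


def run_model_battery(
    full: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    strata: tuple[str, ...] = ("individual", "laboratory"),
) -> pd.DataFrame:
    """Fit both multistratum models for every gene in every replicate.

    Returns a long TestResult table (replicate, model, gene, factor, p,
    p_bh, direction); BH correction is applied per factor, per model, per
    replicate across the genes tested there.
    """
    agg = (
        full.groupby(["rep", "gene_id", "genome_id"], sort=False, observed=True)[["n1", "n0"]]
        .sum()
        .reset_index()
    )
    meta_idx = meta.set_index("genome_id")
    results = []
    for (rep, gene), sub in agg.groupby(["rep", "gene_id"], sort=False, observed=True):
        ms_g = sub.set_index("genome_id").eval("n1/(n1+n0)")
        directions = {}
        for f in FACTOR_ORDER:
            lv = FACTOR_LEVELS[f]
            grp = meta_idx.loc[ms_g.index, f]
            directions[f] = float(
                ms_g[(grp == lv[1]).to_numpy()].mean() - ms_g[(grp == lv[0]).to_numpy()].mean()
            )
        for stratum in strata:
            ps = fit_stratified_model(sub, meta, stratum)
            for f, p in ps.items():
                results.append((rep, stratum, gene, f, p, directions[f]))
    res = pd.DataFrame(results, columns=["rep", "model", "gene_id", "factor", "p", "direction"])
    res["p_bh"] = np.nan
    for (r, mdl, f), sub in res.groupby(["rep", "model", "factor"], observed=True):
        res.loc[sub.index, "p_bh"] = bh_adjust(sub["p"].to_numpy())
    return res


def significant_summary(res: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per model/factor: range of BH-significant gene counts across replicates
    plus the union and intersection of the significant sets."""
    rows = []
    for (mdl, f), sub in res.groupby(["model", "factor"], observed=True):
        per_rep = {
            r: set(s.loc[s["p_bh"] < alpha, "gene_id"]) for r, s in sub.groupby("rep")
        }
        counts = [len(v) for v in per_rep.values()]
        union = set().union(*per_rep.values()) if per_rep else set()
        inter = set.intersection(*per_rep.values()) if per_rep else set()
        n_tested = sub.dropna(subset=["p"]).groupby("rep")["gene_id"].nunique()
        rows.append(
            (mdl, f, min(counts), max(counts), len(union), len(inter),
             int(n_tested.min()) if len(n_tested) else 0)
        )
    return pd.DataFrame(
        rows, columns=["model", "factor", "n_sig_min", "n_sig_max", "n_union", "n_intersection", "n_tested_min"]
    )


# ---------------------------------------------------------------------------
# gene-averaged tests


def gene_averaged_tests(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    factor: str,
    min_individuals: int = 20,
    method: str = "kruskal",
) -> pd.DataFrame:
    """One observation per genome per gene: ANOVA or Kruskal-Wallis screen.

    Genes observed in fewer than ``min_individuals`` genomes (presets
    20/25/30) or with fewer than two factor levels are skipped.  Returns
    per-gene statistic, raw and BH-adjusted p, and for two-level factors
    the direction (second-level mean minus first-level mean).
    """
    if method not in ("kruskal", "anova"):
        raise ValueError("method must be 'kruskal' or 'anova'")
    groups_of = meta.set_index("genome_id")[factor]
    rows = []
    for gene, vals in matrix.iterrows():
        v = vals.dropna()
        if len(v) < min_individuals:
            continue
        grp = groups_of[v.index]
        arrs = [v[grp == lv].to_numpy() for lv in sorted(grp.unique())]
        arrs = [a for a in arrs if len(a)]
        if len(arrs) < 2:
            continue
        flat = np.concatenate(arrs)
        if np.allclose(flat, flat[0]):
            stat, p = 0.0, 1.0
        elif method == "kruskal":
            stat, p = stats.kruskal(*arrs)
        else:
            stat, p = stats.f_oneway(*arrs)
        direction = np.nan
        if len(arrs) == 2:
            direction = float(arrs[1].mean() - arrs[0].mean())
        rows.append((gene, len(v), float(stat), float(p), direction))
    out = pd.DataFrame(rows, columns=["gene_id", "n", "statistic", "p", "direction"])
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out["factor"] = factor
    return out


# ---------------------------------------------------------------------------
# MDS


def mds_profiles(
    matrix: pd.DataFrame,
    exclude: tuple[str, ...] = (),
    k: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) MDS of genomes by Euclidean distance.

    Distances are computed over complete-case genes (rows observed in every
    retained genome).  Returns (coordinates frame indexed by genome with
    columns dim1..dimk, eigenvalues of the doubly-centered matrix).
    """
    keep = [c for c in matrix.columns if c not in set(exclude)]
    if len(keep) < 3:
        raise ValueError("need at least 3 genomes after exclusion")
    sub = matrix[keep].dropna(axis=0, how="any")
    if not len(sub):
        raise ValueError("no complete-case genes for MDS")
    X = sub.T.to_numpy()
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    n = len(keep)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    k_eff = min(k, n - 1)
    lam = np.clip(evals[:k_eff], 0, None)
    lam[lam < 1e-12 * max(lam.max(), 1e-300)] = 0.0  # numerical-zero modes
    coords = evecs[:, :k_eff] * np.sqrt(lam)
    frame = pd.DataFrame(coords, index=pd.Index(keep, name="genome"),
                         columns=[f"dim{i + 1}" for i in range(k_eff)])
    return frame, evals


# ---------------------------------------------------------------------------
# chrX sex analysis


def chrx_sex_test(
    chrx_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every chrX gene for sex differences under both model variants.

    ``chrx_matrix`` is a genes x genomes frame of autosome-normalized chrX
    MS values (gene MS divided by the genome's autosomal pooled mean).  The
    ``individual`` variant is a one-way ANOVA of the per-genome values by
    sex; the ``laboratory`` variant tests sex in the between-laboratory
    stratum.  Returns (TestResult table, per-sex summaries).
    """
    meta_idx = meta.set_index("genome_id")
    sexes = meta_idx.loc[chrx_matrix.columns, "sex"]
    if sexes.nunique() < 2:
        raise ValueError("single-sex cohort: sex effect untestable")
    rows = []
    for gene, vals in chrx_matrix.iterrows():
        v = vals.dropna()
        if len(v) < 3:
            continue
        sx = sexes[v.index]
        labs = meta_idx.loc[v.index, "laboratory"]
        for variant in ("individual", "laboratory"):
            if variant == "individual":
                y, w = v.to_numpy(float), np.ones(len(v))
                x = (sx == "XY").to_numpy(float)
            else:
                g = pd.DataFrame({"lab": labs.to_numpy(), "y": v.to_numpy(float),
                                  "x": (sx == "XY").to_numpy(float)}).groupby("lab")
                y = g["y"].mean().to_numpy()
                x = g["x"].mean().to_numpy()
                w = g.size().to_numpy(float)
            if len(y) < 3:
                rows.append((variant, gene, np.nan, np.nan))
                continue
            ss_terms, rss, df_resid, total = _seq_weighted_anova(y, w, {"sex": x})
            ss, est = ss_terms["sex"]
            if not est or df_resid < 1 or total <= 0:
                rows.append((variant, gene, np.nan, np.nan))
                continue
            if rss <= 1e-300:
                p = np.nan if ss <= 1e-300 else 0.0
                if ss <= 1e-300:
                    p = 1.0  # constant response: no signal
            else:
                p = float(stats.f.sf(ss / (rss / df_resid), 1, df_resid))
            direction = float(v[(sx == "XY").to_numpy()].mean() - v[(sx == "XX").to_numpy()].mean())
            rows.append((variant, gene, p, direction))
    res = pd.DataFrame(rows, columns=["model", "gene_id", "p", "direction"])
    res["p_bh"] = np.nan
    for variant, sub in res.groupby("model"):
        res.loc[sub.index, "p_bh"] = bh_adjust(sub["p"].to_numpy())
    summaries = []
    for sex in ("XX", "XY"):
        cols = [c for c in chrx_matrix.columns if sexes[c] == sex]
        vals = chrx_matrix[cols].to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        summaries.append((sex, len(cols), float(np.median(vals)), float(np.mean(vals))))
    summaries = pd.DataFrame(summaries, columns=["sex", "n_genomes", "median", "mean"])
    return res, summaries


# ---------------------------------------------------------------------------
# co-directionality against external differential-methylation tables


def delta_ms(matrix: pd.DataFrame, meta: pd.DataFrame, genomes: list[str] | None = None) -> pd.Series:
    """Per-gene δMS(F−HG): mean NF cell minus mean HG cell of the matrix."""
    cols = list(matrix.columns if genomes is None else [c for c in matrix.columns if c in set(genomes)])
    grp = meta.set_index("genome_id").loc[cols, "subsistence"]
    nf = matrix[[c for c in cols if grp[c] == "NF"]].mean(axis=1)
    hg = matrix[[c for c in cols if grp[c] == "HG"]].mean(axis=1)
    return (nf - hg).dropna()


def codirectionality(a: pd.Series, b: pd.Series, min_overlap: int = 3) -> dict:
    """Spearman rank correlation of two per-gene effect tables over shared genes."""
    common = a.dropna().index.intersection(b.dropna().index)
    if len(common) < min_overlap:
        raise ValueError(f"only {len(common)} overlapping genes (< {min_overlap})")
    r, p = stats.spearmanr(a[common], b[common])
    return {"n": int(len(common)), "r": float(r), "p": float(p)}


def codirectionality_matrix(tables: dict[str, pd.Series], min_overlap: int = 3) -> pd.DataFrame:
    """All-pairs comparison: Spearman r in the upper triangle, p in the lower."""
    names = list(tables)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            nj = names[j]
            res = codirectionality(tables[ni], tables[nj], min_overlap)
            out.loc[ni, nj] = res["r"]
            out.loc[nj, ni] = res["p"]
    return out
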