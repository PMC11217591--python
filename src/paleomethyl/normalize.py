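"""Monte Carlo read-subsampling normalization to a common pooled mean MS.

Mean methylation scores differ several-fold between ancient genomes for
technical reasons (damage rates, coverage, protocol).  To compare genomes,
reads are randomly subsampled so that every genome attains the same pooled
mean MS target t (default 0.02, the low end of the observed range):

* genome below target — keep every deaminated read, draw
  ``round(((1-t)/t) * N1)`` non-deaminated reads from the genome-wide pool
  (for t = 0.02 the classic 49x rule);
* genome above target — symmetric, subsample the deaminated reads to
  ``round(N0 / ((1-t)/t))``.

Sampling is uniform without replacement over the genome-wide read pool,
which allocates retained reads across sites as a multivariate
hypergeometric draw.  Repeating the subsampling R times (default 20) with
independent seeds yields replicate datasets whose gene sets differ
slightly, as sites whose retained total drops to zero vanish.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_TARGET = 0.02
DEFAULT_REPLICATES = 20


class NormalizationInfeasible(ValueError):
    """The target pooled mean cannot be reached for a genome."""


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def normalize_genome(
    counts: pd.DataFrame,
    target_ms: float = DEFAULT_TARGET,
    seed: int | np.random.Generator = 0,
    genome_id: str = "?",
) -> pd.DataFrame:
    """Subsample one genome's per-site counts to the target pooled mean MS.

    ``counts`` columns: chrom, pos, n1, n0.  Returns the same schema with
    subsampled (n1, n0); sites left with zero reads are dropped.  A genome
    already at the target within one read is returned unchanged.
    """
    if not 0 < target_ms < 1:
        raise ValueError("target_ms must be in (0,1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = counts["n1"].to_numpy(np.int64)
    n0 = counts["n0"].to_numpy(np.int64)
    N1, N0 = int(n1.sum()), int(n0.sum())
    if N1 + N0 == 0:
        raise NormalizationInfeasible(f"genome {genome_id}: no reads to normalize")
    ratio = (1 - target_ms) / target_ms
    mean = N1 / (N1 + N0)
    out = counts[["chrom", "pos"]].copy()
    if _round_half_away(ratio * N1) == N0:
        # already at target within one read
        out["n1"], out["n0"] = n1, n0
    elif mean < target_ms:
        n0_keep = _round_half_away(ratio * N1)
        if N1 == 0 or n0_keep > N0:
            raise NormalizationInfeasible(
                f"genome {genome_id}: cannot raise pooled mean {mean:.4g} to {target_ms}"
            )
        out["n1"] = n1
        out["n0"] = rng.multivariate_hypergeometric(n0, n0_keep)
    else:
        n1_keep = _round_half_away(N0 / ratio)
        if N0 == 0 or n1_keep > N1:
            raise NormalizationInfeasible(
                f"genome {genome_id}: cannot lower pooled mean {mean:.4g} to {target_ms}"
            )
        out["n1"] = rng.multivariate_hypergeometric(n1, n1_keep)
        out["n0"] = n0
    out = out[(out["n1"] + out["n0"]) > 0].reset_index(drop=True)
    return out


def make_replicates(
    per_genome: dict[str, pd.DataFrame],
    target_ms: float = DEFAULT_TARGET,
    n_replicates: int = DEFAULT_REPLICATES,
    base_seed: int = 0,
) -> tuple[list[dict[str, pd.DataFrame]], pd.DataFrame]:
    """R independent normalized replicate datasets plus a manifest.

    Replicate r of genome g uses a generator seeded deterministically from
    (base_seed, r, g), so a fixed base seed reproduces every replicate
    byte-for-byte.  The manifest records achieved pooled means.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    replicates = []
    manifest_rows = []
    genome_ids = list(per_genome)
    for r in range(1, n_replicates + 1):
        rep = {}
        for gi, gid in enumerate(genome_ids):
            rng = np.random.default_rng(np.random.SeedSequence([base_seed, r, gi]))
            sub = normalize_genome(per_genome[gid], target_ms, rng, genome_id=gid)
            rep[gid] = sub
            tot1, tot0 = int(sub["n1"].sum()), int(sub["n0"].sum())
            manifest_rows.append(
                (r, gid, base_seed, tot1, tot0, tot1 / (tot1 + tot0))
            )
        replicates.append(rep)
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["replicate", "genome_id", "base_seed", "n1_total", "n0_total", "achieved_ms"],
    )
    return replicates, manifest


def normalize_chrx(
    chrx_values: pd.DataFrame,
    autosomal_mean: pd.Series | dict[str, float],
) -> pd.DataFrame:
    """Scale chrX MS values by each genome's autosomal pooled mean MS.

    ``chrx_values`` is a sites-or-genes x genomes frame of chrX MS values;
    ``autosomal_mean`` maps genome id to its autosomal pooled mean.  Raises
    if any genome's autosomal mean is zero or missing.
    """
    autosomal_mean = pd.Series(autosomal_mean)
    missing = [g for g in chrx_values.columns if g not in autosomal_mean.index]
    if missing:
        raise ValueError(f"no autosomal mean for genomes: {missing}")
    means = autosomal_mean[chrx_values.columns]
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"autosomal pooled mean is zero for genomes: {bad}")
    return chrx_values.div(means, axis=1)
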