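"""Damage-based methylation scoring of UDG-treated aligned reads.

After UDG treatment, postmortem deamination of *methylated* cytosines
survives as C→T mismatches concentrated at fragment termini, while
deaminated unmethylated cytosines are excised.  The methylation score of a
CpG site is therefore MS = n1/(n0+n1), with n1 the deaminated and n0 the
non-deaminated reads inspecting that site.

A read inspects a site only where the damage signal lives: when the site's
C (forward-orientation reads) or G (reverse orientation, mirrored G→A)
falls within ``damage_window`` bases of an eligible read end — the 5' end
for double-stranded libraries, both ends for single-stranded ones.  A read
contributes at most once per site; when both ends are eligible the 5' end
wins.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator

import numpy as np
import pandas as pd

DEFAULT_MIN_LENGTH = 35
DEFAULT_MIN_MAPQ = 30
DEFAULT_MAX_MISMATCH_FRAC = 0.10
DEFAULT_DAMAGE_WINDOW = 2
DEPTH_PRESETS = {"standard": 4, "strict": 10}

COUNT_COLS = ["chrom", "pos", "n1", "n0"]


def filter_reads(
    reads: Iterable,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> Iterator:
    """Yield pysam reads passing the length/MAPQ/mismatch filters.

    Drops unmapped, secondary, supplementary and duplicate-flagged reads;
    keeps reads with length >= 35 bp, MAPQ >= 30 and at most 10% mismatches
    (NM tag over aligned length) under the default thresholds.
    """
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        length = read.query_length or 0
        if length < min_length or read.mapping_quality < min_mapq:
            continue
        if not read.has_tag("NM"):
            raise ValueError(f"read {read.query_name} lacks an NM tag; cannot compute mismatches")
        if read.get_tag("NM") / length > max_mismatch_frac:
            continue
        yield read


def eligible_inspections(
    starts: np.ndarray,
    ends: np.ndarray,
    is_reverse: np.ndarray,
    library: str,
    window: int = DEFAULT_DAMAGE_WINDOW,
) -> pd.DataFrame:
    """Candidate (read, site) inspections implied by the terminal-window rule.

    For each read, lists the reference positions whose CpG evidence the read
    may carry: ``site_pos`` is the catalog key (the forward-strand C),
    ``base_pos`` the reference position whose base is inspected (the C
    itself on forward reads, the G at C+1 on reverse reads).  Candidates are
    not yet intersected with any catalog.  Duplicate (read, site) pairs from
    overlapping end windows are removed with the 5'-end entry kept.
    """
    if library not in ("ss", "ds"):
        raise ValueError(f"library must be 'ss' or 'ds', got {library!r}")
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    is_reverse = np.asarray(is_reverse, dtype=bool)
    lengths = ends - starts
    n = len(starts)
    idx = np.arange(n)
    blocks = []  # appended in 5'-first priority order

    def block(read_idx, base_pos, site_pos):
        blocks.append(
            pd.DataFrame({"read_idx": read_idx, "base_pos": base_pos, "site_pos": site_pos})
        )

    for k in range(window):
        ok = (lengths > k) & ~is_reverse
        p = starts[ok] + k  # forward 5' end: inspect the C
        block(idx[ok], p, p)
        ok = (lengths > k) & is_reverse
        q = ends[ok] - 1 - k  # reverse 5' end: inspect the G at C+1
        block(idx[ok], q, q - 1)
    if library == "ss":
        for k in range(window):
            ok = (lengths > k) & ~is_reverse
            p = ends[ok] - 1 - k  # forward 3' end
            block(idx[ok], p, p)
            ok = (lengths > k) & is_reverse
            q = starts[ok] + k  # reverse 3' end
            block(idx[ok], q, q - 1)
    cand = pd.concat(blocks, ignore_index=True)
    cand = cand.drop_duplicates(["read_idx", "site_pos"], keep="first")
    return cand.reset_index(drop=True)


def _catalog_positions(catalog: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in catalog.groupby("chrom", observed=True)
    }


def _in_sorted(values: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    if not len(sorted_arr):
        return np.zeros(len(values), dtype=bool)
    i = np.searchsorted(sorted_arr, values)
    i_c = np.clip(i, 0, len(sorted_arr) - 1)
    return sorted_arr[i_c] == values


def count_site_evidence(
    bam_path: str,
    catalog: pd.DataFrame,
    library: str,
    damage_window: int = DEFAULT_DAMAGE_WINDOW,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> pd.DataFrame:
    """Count deaminated/non-deaminated evidence per catalog CpG from a BAM.

    Returns a frame (chrom, pos, n1, n0, ms) with one row per site holding
    at least one informative read.  T (or A on reverse orientation) at the
    inspected base counts as deaminated, C (or G) as non-deaminated; any
    other base is ignored.
    """
    import pysam

    cat_pos = _catalog_positions(catalog)
    bam_chroms = None
    counts: dict[tuple[str, int], list[int]] = {}
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        bam_chroms = set(bam.references)
        unknown = {c for c in cat_pos if c not in bam_chroms}
        if unknown:
            raise ValueError(f"catalog chromosomes absent from BAM header: {sorted(unknown)}")
        cat_sets = {c: set(map(int, p)) for c, p in cat_pos.items()}
        w = damage_window
        for read in filter_reads(bam.fetch(), min_length, min_mapq, max_mismatch_frac):
            chrom = read.reference_name
            sites = cat_sets.get(chrom)
            if not sites:
                continue
            start, end = read.reference_start, read.reference_end
            rev = read.is_reverse
            length = end - start
            # candidate (base_pos, site_pos) pairs, 5'-end entries first
            cand: list[tuple[int, int]] = []
            seen: set[int] = set()
            ks = range(min(w, length))
            if not rev:
                ends_ = [(start + k, start + k) for k in ks]
                if library == "ss":
                    ends_ += [(end - 1 - k, end - 1 - k) for k in ks]
            else:
                ends_ = [(end - 1 - k, end - 2 - k) for k in ks]
                if library == "ss":
                    ends_ += [(start + k, start + k - 1) for k in ks]
            for bpos, spos in ends_:
                if spos in sites and spos not in seen:
                    seen.add(spos)
                    cand.append((bpos, spos))
            if not cand:
                continue
            cig = read.cigarstring or ""
            if "I" in cig or "D" in cig or "S" in cig:
                # indel/clip-containing alignments: map reference -> query
                # explicitly and skip unaligned positions
                ref2q = {r: q for q, r in read.get_aligned_pairs(matches_only=True)}
            else:
                ref2q = None
            seq = read.query_sequence
            for bpos, spos in cand:
                qi = ref2q.get(bpos) if ref2q is not None else bpos - start
                if qi is None:
                    continue
                base = seq[qi]
                if rev:
                    dea = base == "A"
                    non = base == "G"
                else:
                    dea = base == "T"
                    non = base == "C"
                if not (dea or non):
                    continue
                key = (chrom, spos)
                if key not in counts:
                    counts[key] = [0, 0]
                counts[key][0 if dea else 1] += 1
    rows = [(c, p, v[0], v[1]) for (c, p), v in counts.items()]
    out = pd.DataFrame(rows, columns=COUNT_COLS)
    out = out.sort_values(["chrom", "pos"], ignore_index=True)
    return with_ms(out)


def count_site_evidence_table(
    reads: pd.DataFrame,
    damaged: pd.DataFrame,
    catalog: pd.DataFrame,
    library: str,
    damage_window: int = DEFAULT_DAMAGE_WINDOW,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> pd.DataFrame:
    """Vectorized counterpart of :func:`count_site_evidence` for in-memory reads.

    ``reads`` has columns (read_id, chrom, start, end, is_reverse);
    ``damaged`` lists the deaminated base edits as (read_id, base_pos).
    The read's base at any other inspected position is the reference base.
    """
    reads = reads[(reads["end"] - reads["start"]) >= min_length].reset_index(drop=True)
    cat_pos = _catalog_positions(catalog)
    out_frames = []
    dam_key = None
    if len(damaged):
        dam_key = pd.MultiIndex.from_arrays([damaged["read_id"], damaged["base_pos"]])
    for chrom, sub in reads.groupby("chrom", observed=True):
        pos_arr = cat_pos.get(chrom)
        if pos_arr is None or not len(pos_arr):
            continue
        sub = sub.reset_index(drop=True)
        cand = eligible_inspections(
            sub["start"].to_numpy(), sub["end"].to_numpy(), sub["is_reverse"].to_numpy(),
            library, damage_window,
        )
        cand = cand[_in_sorted(cand["site_pos"].to_numpy(), pos_arr)]
        if not len(cand):
            continue
        rid = sub["read_id"].to_numpy()[cand["read_idx"].to_numpy()]
        key = pd.MultiIndex.from_arrays([rid, cand["base_pos"].to_numpy()])
        dea = key.isin(dam_key) if dam_key is not None else np.zeros(len(cand), dtype=bool)
        g = pd.DataFrame({"pos": cand["site_pos"].to_numpy(), "dea": dea}).groupby("pos")["dea"]
        agg = g.agg(n1="sum", total="count").reset_index()
        agg["n0"] = agg["total"] - agg["n1"]
        agg["chrom"] = chrom
        out_frames.append(agg[COUNT_COLS])
    if not out_frames:
        return with_ms(pd.DataFrame(columns=COUNT_COLS))
    out = pd.concat(out_frames, ignore_index=True).sort_values(["chrom", "pos"], ignore_index=True)
    return with_ms(out)


def with_ms(counts: pd.DataFrame) -> pd.DataFrame:
    counts = counts.copy()
    total = counts["n1"] + counts["n0"]
    with np.errstate(invalid="ignore"):
        counts["ms"] = np.where(total > 0, counts["n1"] / total.replace(0, np.nan), np.nan)
    return counts


def apply_depth_filter(counts: pd.DataFrame, min_depth: int = 4) -> pd.DataFrame:
    """Keep sites with at least ``min_depth`` informative reads (presets 4 / 10)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    keep = (counts["n1"] + counts["n0"]) >= min_depth
    return counts[keep].reset_index(drop=True)


def pool_mean_ms(counts: pd.DataFrame) -> tuple[float, int, int]:
    """Read-weighted pooled mean MS: sum(n1) / (sum(n0) + sum(n1))."""
    if not len(counts):
        raise ValueError("cannot pool an empty site set")
    n1 = int(counts["n1"].sum())
    n0 = int(counts["n0"].sum())
    if n1 + n0 == 0:
        raise ValueError("cannot pool a site set with zero reads")
    return n1 / (n1 + n0), n1, n0


def assemble_matrix(per_genome) -> pd.DataFrame:
    """Outer-join per-genome MS columns on (chrom, pos); missing stays NaN.

    Accepts a mapping of genome id to counts or an iterable of (id, counts)
    pairs; duplicate genome ids are rejected.
    """
    items = list(per_genome.items()) if hasattr(per_genome, "items") else list(per_genome)
    ids = [g for g, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    cols = {}
    for gid, counts in items:
        c = counts if "ms" in counts else with_ms(counts)
        cols[gid] = c.set_index(["chrom", "pos"])["ms"]
    mat = pd.DataFrame(cols)
    mat.columns.name = "genome"
    return mat.sort_index()


def context_summary(
    per_genome: dict[str, pd.DataFrame], catalog: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome mean site MS per context class, plus island-vs-other tests.

    Returns ``(means, tests)``: ``means`` is genomes x context classes;
    ``tests`` holds a paired one-sided Wilcoxon signed-rank p-value per
    non-island class for the hypothesis that island means are lower,
    computed across genomes.
    """
    from scipy.stats import wilcoxon

    ctx = catalog.set_index(["chrom", "pos"])["context"]
    rows = {}
    for gid, counts in per_genome.items():
        c = counts if "ms" in counts else with_ms(counts)
        joined = c.set_index(["chrom", "pos"]).join(ctx, how="inner")
        rows[gid] = joined.groupby("context", observed=False)["ms"].mean()
    means = pd.DataFrame(rows).T
    means.index.name = "genome"
    tests = []
    if "island" in means:
        isl = means["island"]
        for cls in means.columns:
            if cls == "island":
                continue
            pair = pd.DataFrame({"island": isl, "other": means[cls]}).dropna()
            if len(pair) < 1:
                continue
            diff = pair["island"] - pair["other"]
            if (diff == 0).all():
                stat, p = 0.0, 1.0
            else:
                stat, p = wilcoxon(pair["island"], pair["other"], alternative="less")
            tests.append((cls, len(pair), float(stat), float(p)))
    tests = pd.DataFrame(tests, columns=["vs_class", "n_genomes", "statistic", "p"])
    return means, tests
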