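"""CpG-position catalog, genomic-context classification and gene models.

The catalog lists every CG dinucleotide on the requested chromosomes, keyed
by the 0-based position of the C on the forward strand (reverse-strand
evidence is folded onto the same key by the scoring module).  Sites
overlapping a SNP exclusion mask are dropped so that genetic variation at
CpG positions cannot masquerade as methylation signal.

Context classes follow the standard CpG-island geography: ``island`` inside
an annotated CGI, ``shore5``/``shore3`` within 2 kb up/downstream of an
island, ``shelf5``/``shelf3`` within the next 2 kb, and ``open_sea``
elsewhere.  Where flanks of adjacent islands overlap the nearer island
assigns the tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SHORE_BP = 2_000
SHELF_BP = 2_000
PROMOTER_UP_BP = 2_000
PROMOTER_LEN_BP = 4_000

CONTEXT_CLASSES = ("island", "shore5", "shore3", "shelf5", "shelf3", "open_sea")


@dataclass
class GeneModel:
    """A gene as a union span of its exons plus a derived 4 kb promoter.

    The promoter is centered on the 5'-most exon boundary: 2 kb upstream plus
    2 kb downstream of the first exon start (mirrored for minus-strand genes),
    clipped at chromosome bounds.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def promoter(self, chrom_length: int | None = None) -> tuple[int, int]:
        if self.strand == "-":
            anchor = self.end
            lo, hi = anchor - PROMOTER_UP_BP, anchor + PROMOTER_UP_BP
        else:
            anchor = self.start
            lo, hi = anchor - PROMOTER_UP_BP, anchor + PROMOTER_UP_BP
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return lo, hi


def catalog_cpgs(
    sequences: dict[str, str],
    snp_mask: pd.DataFrame | None = None,
    chromosomes: list[str] | None = None,
) -> pd.DataFrame:
    """Scan reference sequences for CG dinucleotides and drop masked sites.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to uppercase sequence string.
    snp_mask
        BED-style frame with columns ``chrom``, ``start``, ``end``
        (0-based half-open).  A CpG is removed when its C or G position
        overlaps any mask interval.
    chromosomes
        Restrict the catalog to these chromosomes (default: all).

    Returns
    -------
    DataFrame with columns ``chrom``, ``pos`` (0-based position of the C)
    and ``chrom_class`` (``chrX`` or ``autosome``), sorted by position.
    """
    if snp_mask is not None:
        unknown = set(snp_mask["chrom"]) - set(sequences)
        if unknown:
            raise ValueError(f"mask chromosomes absent from reference: {sorted(unknown)}")
    frames = []
    for chrom in chromosomes if chromosomes is not None else sequences:
        seq = np.frombuffer(sequences[chrom].upper().encode(), dtype="S1")
        pos = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        if snp_mask is not None:
            sub = snp_mask[snp_mask["chrom"] == chrom]
            if len(sub):
                keep = np.ones(len(pos), dtype=bool)
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                for p_off in (0, 1):  # both the C and the G may hit the mask
                    q = pos + p_off
                    idx = np.searchsorted(starts, q, side="right") - 1
                    hit = (idx >= 0) & (q < ends[np.clip(idx, 0, None)])
                    keep &= ~hit
                pos = pos[keep]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "chrom_class": "chrX" if chrom in ("chrX", "X") else "autosome",
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "chrom_class"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], ignore_index=True)


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent BED intervals per chromosome."""
    out = []
    for chrom, sub in intervals.groupby("chrom"):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _classify_positions(pos: np.ndarray, islands: pd.DataFrame) -> np.ndarray:
    """Context class per position against merged island intervals of one chromosome."""
    ctx = np.full(len(pos), "open_sea", dtype=object)
    if not len(islands):
        return ctx
    starts = islands["start"].to_numpy()
    ends = islands["end"].to_numpy()
    # signed distance to the nearest island: 0 inside, <0 upstream of island
    # start, >0 downstream of island end; nearest island wins, ties resolved
    # toward the more island-proximal tier by taking the minimum |distance|.
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    # distance to previous island end (downstream flank) and next start (upstream flank)
    prev_end = np.where(idx >= 0, ends[np.clip(idx, 0, None)], -np.inf)
    nxt = np.clip(idx + 1, 0, len(starts) - 1)
    next_start = np.where(idx + 1 < len(starts), starts[nxt], np.inf)
    d_down = pos - prev_end + 1  # 1-based distance past the island end
    d_up = next_start - pos  # distance to the next island start
    ctx[inside] = "island"
    out = ~inside
    use_down = d_down <= d_up  # nearer feature wins; tie -> downstream (equal tier)
    dist = np.where(use_down, d_down, d_up)
    tier_shore = out & (dist <= SHORE_BP)
    tier_shelf = out & (dist > SHORE_BP) & (dist <= SHORE_BP + SHELF_BP)
    ctx[tier_shore & use_down] = "shore3"
    ctx[tier_shore & ~use_down] = "shore5"
    ctx[tier_shelf & use_down] = "shelf3"
    ctx[tier_shelf & ~use_down] = "shelf5"
    return ctx


def classify_context(sites: pd.DataFrame, cgi_track: pd.DataFrame) -> pd.DataFrame:
    """Assign island/shore/shelf/open-sea context to each catalog site.

    ``cgi_track`` is a BED-style frame (chrom, start, end); overlapping
    islands are merged first.  Returns a copy of ``sites`` with a
    ``context`` column.  Idempotent and independent of row order.
    """
    sites = sites.copy()
    sites["context"] = "open_sea"
    if len(cgi_track):
        merged = merge_intervals(cgi_track)
        for chrom, sub in sites.groupby("chrom"):
            isl = merged[merged["chrom"] == chrom]
            sites.loc[sub.index, "context"] = _classify_positions(
                sub["pos"].to_numpy(), isl
            )
    sites["context"] = pd.Categorical(sites["context"], categories=CONTEXT_CLASSES)
    return sites


def derive_gene_intervals(exon_table: pd.DataFrame) -> list[GeneModel]:
    """Build gene models from a UCSC-style exon table.

    Expected columns: ``gene_id``, ``chrom``, ``strand``, ``exon_start``
    (0-based), ``exon_end`` (1-based, i.e. half-open after conversion —
    UCSC convention, used as-is since half-open end equals the 1-based
    inclusive end).
    """
    genes: list[GeneModel] = []
    for gene_id, sub in exon_table.groupby("gene_id", sort=True):
        chroms = sub["chrom"].unique()
        if len(chroms) > 1:
            raise ValueError(f"gene {gene_id} has exons on multiple chromosomes: {list(chroms)}")
        strand = sub["strand"].iloc[0]
        exons = sorted(zip(sub["exon_start"].astype(int), sub["exon_end"].astype(int)))
        genes.append(GeneModel(str(gene_id), chroms[0], strand, exons))
    return genes


def gene_table(genes: list[GeneModel], chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Flatten gene models into a frame of gene spans and promoters."""
    rows = []
    for g in genes:
        L = chrom_lengths.get(g.chrom) if chrom_lengths else None
        plo, phi = g.promoter(L)
        rows.append((g.gene_id, g.chrom, g.strand, g.start, g.end, plo, phi))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "strand", "start", "end", "promoter_start", "promoter_end"],
    )
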