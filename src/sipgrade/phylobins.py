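"""Phylobins: contig sets keyed by enrichment status and order-rank taxonomy.

A phylobin is the genomic-ecological unit of the analysis — all contigs
sharing a ¹³C-enrichment status (strong, weak or unenriched) and a
taxonomic order.  Bimodal and undetermined contigs enter no phylobin and
are reported separately.  Quality filters (>1 Mb total length, >75 %
completeness when supplied) and the four phylobin categories (enrichment
status × cellulolytic potential) follow here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .traits import is_cellulolytic

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
BINNED_STATUSES = ("strong", "weak", "unenriched")


@dataclass
class Phylobin:
    status: str
    order: str
    contig_ids: list[str]
    total_bp: int
    completeness: float | None = None
    ssu_abundance: float | None = None
    category: str | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.status, self.order)

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)


def rank_at_order(lineage) -> str:
    """Order-rank label of a ranked lineage, or an 'unclassified_' fallback.

    Accepts a semicolon-delimited string or a sequence ordered
    domain → species; absent ranks may only trail.  If the order rank is
    unresolved the label is "unclassified_" + the lowest resolved rank.
    """
    if isinstance(lineage, str):
        parts = [p.strip() for p in lineage.split(";")]
    else:
        parts = [str(p).strip() for p in lineage]
    parts = [p for p in parts if p]
    if not parts:
        raise ValueError("empty lineage")
    if len(parts) > RANKS.index("order"):
        return parts[RANKS.index("order")]
    return f"unclassified_{parts[-1]}"


def build_phylobins(
    calls: pd.Series | dict,
    taxonomy: pd.Series | dict,
    lengths: pd.Series | dict,
) -> tuple[list[Phylobin], pd.DataFrame]:
    """Partition classified contigs into phylobins.

    ``calls`` maps contig id → enrichment call, ``taxonomy`` maps contig
    id → lineage (string or sequence), ``lengths`` maps contig id → bp.
    Returns (phylobins, excluded) where ``excluded`` lists the bimodal
    and undetermined contigs with their calls.  Contigs with a call but
    no taxonomy are routed to an "unclassified_root" bin.
    """
    calls = pd.Series(calls)
    lengths = pd.Series(lengths)
    taxonomy = dict(taxonomy) if not isinstance(taxonomy, pd.Series) else taxonomy.to_dict()
    bins: dict[tuple[str, str], Phylobin] = {}
    excluded_rows = []
    for cid, call in calls.items():
        if call not in BINNED_STATUSES:
            excluded_rows.append({"contig_id": cid, "call": call})
            continue
        if cid in taxonomy:
            order = rank_at_order(taxonomy[cid])
        else:
            logger.warning("contig %s has a call but no taxonomy; routing to unclassified_root", cid)
            order = "unclassified_root"
        key = (call, order)
        if key not in bins:
            bins[key] = Phylobin(status=call, order=order, contig_ids=[], total_bp=0)
        pb = bins[key]
        pb.contig_ids.append(cid)
        pb.total_bp += int(lengths[cid])
    excluded = pd.DataFrame(excluded_rows, columns=["contig_id", "call"])
    return sorted(bins.values(), key=lambda b: b.key), excluded


def filter_quality(
    phylobins: list[Phylobin],
    min_bp: int = 1_000_000,
    min_completeness: float = 75.0,
) -> list[Phylobin]:
    """Retain phylobins strictly greater than 1 Mb and, when completeness
    is known, strictly greater than 75 % complete."""
    if min_bp <= 0 or min_completeness <= 0:
        raise ValueError("thresholds must be > 0")
    return [
        b for b in phylobins
        if b.total_bp > min_bp
        and (b.completeness is None or b.completeness > min_completeness)
    ]


def categorize(phylobin: Phylobin, annotations: pd.DataFrame) -> str:
    """Four-way phylobin category from enrichment status × cellulolytic flag.

    A phylobin is cellulolytic iff any member contig carries an
    endoglucanase-set family; unenriched phylobins stay "unenriched"
    regardless of annotations.
    """
    if phylobin.status == "unenriched":
        phylobin.category = "unenriched"
        return phylobin.category
    member = annotations[annotations["unit_id"].isin(phylobin.contig_ids)]
    flag = is_cellulolytic(member) if len(member) else False
    phylobin.category = f"{phylobin.status}_{'cellulolytic' if flag else 'noncellulolytic'}"
    return phylobin.category


def ssu_abundance(ssu_counts: pd.Series | dict, phylobins: list[Phylobin] | None = None) -> pd.DataFrame:
    """Relative SSU rRNA fragment abundance per order, ranked descending.

    Ties rank alphabetically (stable).  When phylobins are given, their
    ``ssu_abundance`` fields are filled in by order label.
    """
    counts = pd.Series(ssu_counts, dtype=float)
    if counts.empty:
        raise ValueError("empty SSU table")
    if (counts < 0).any():
        raise ValueError("SSU counts must be >= 0")
    rel = counts / counts.sum()
    out = (
        rel.rename("relative_abundance")
        .reset_index()
        .rename(columns={"index": "order"})
        .sort_values(["relative_abundance", "order"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    out["rank"] = range(1, len(out) + 1)
    if phylobins is not None:
        lut = dict(zip(out["order"], out["relative_abundance"]))
        for b in phylobins:
            b.ssu_abundance = lut.get(b.order)
    return out


def phylobin_table(phylobins: list[Phylobin]) -> pd.DataFrame:
    """Summary table (one row per phylobin)."""
    return pd.DataFrame(
        [
            {
                "status": b.status,
                "order": b.order,
                "n_contigs": b.n_contigs,
                "total_bp": b.total_bp,
                "completeness": b.completeness,
                "category": b.category,
                "ssu_abundance": b.ssu_abundance,
            }
            for b in phylobins
        ]
    )
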