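"""Promoter scanning for the palindromic CRE element.

CREB1, once phosphorylated, binds the cAMP-responsive element in target-gene
promoters.  The canonical consensus is the palindromic octamer TGACGTCA: its
reverse complement is itself, so an exact single-strand scan already covers
both strands.  That strand-completeness is checked at runtime for whatever
motif is supplied and logged; for non-palindromic motifs the scan covers the
given strand only.

Matching is exact string equality — no position-weight-matrix scoring — and
N never matches.  Overlapping occurrences are all reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParameterError
from .target_consensus import reverse_complement

logger = logging.getLogger(__name__)

CRE_MOTIF = "TGACGTCA"

_VALID = set("ACGTN")


@dataclass(frozen=True)
class CREHit:
    """An exact motif occurrence, 0-based half-open on the given promoter strand."""

    gene: str
    start: int
    end: int
    matched: str


def find_cre_sites(
    promoter: str, motif: str = CRE_MOTIF, gene: str = ""
) -> list[CREHit]:
    """Every start index of an exact occurrence of ``motif`` in ``promoter``.

    Overlapping occurrences are reported individually.  Scans the given
    strand; if the motif is its own reverse complement the single-strand scan
    is provably strand-complete (checked and logged).
    """
    promoter = promoter.upper()
    motif = motif.upper()
    if len(motif) < 4:
        raise ParameterError("motif must be >= 4 nt")
    bad = (set(promoter) | set(motif)) - _VALID
    if bad:
        raise ParameterError(f"invalid nucleotide(s) {sorted(bad)}")
    if motif == reverse_complement(motif):
        logger.debug("motif %s is palindromic: single-strand scan is strand-complete", motif)
    else:
        logger.warning("motif %s is not palindromic: scanning given strand only", motif)

    hits = []
    i = promoter.find(motif)
    while i != -1:
        hits.append(CREHit(gene, i, i + len(motif), motif))
        i = promoter.find(motif, i + 1)
    return hits


def scan_promoters(
    promoters: Mapping[str, str], motif: str = CRE_MOTIF
) -> dict[str, list[CREHit]]:
    """Scan a promoter set; returns per-gene hit lists (empty lists kept)."""
    return {g: find_cre_sites(seq, motif, gene=g) for g, seq in promoters.items()}


def intersect_with_gene_set(
    hits: Mapping[str, Sequence[CREHit]],
    downregulated: Iterable[str],
) -> pd.DataFrame:
    """Cross a CRE hit table with a down-regulated gene set.

    Returns one row per gene (union of scanned and down-regulated genes,
    case-insensitively harmonized) with columns ``gene``, ``n_cre``,
    ``in_downregulated_set`` and ``first_hit_offset`` (pandas NA when the
    gene has no hit), sorted by ``n_cre`` descending then gene id.
    Candidate CREB1 targets are the rows with both flags:
    ``in_downregulated_set & (n_cre >= 1)``.
    """
    down = {g.casefold(): g for g in downregulated}
    if not down:
        logger.warning("empty down-regulated gene set: no candidates possible")
    scanned = {g.casefold(): g for g in hits}
    rows = []
    for key in sorted(set(down) | set(scanned)):
        gene = scanned.get(key, down.get(key))
        gene_hits = hits.get(scanned.get(key, ""), [])
        rows.append(
            {
                "gene": gene,
                "n_cre": len(gene_hits),
                "in_downregulated_set": key in down,
                "first_hit_offset": min((h.start for h in gene_hits), default=pd.NA),
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "n_cre", "in_downregulated_set",
                                        "first_hit_offset"])
    table = table.sort_values(
        ["n_cre", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def candidate_genes(table: pd.DataFrame) -> list[str]:
    """Down-regulated genes carrying >=1 CRE element, in table order."""
    mask = table["in_downregulated_set"] & (table["n_cre"] >= 1)
    return table.loc[mask, "gene"].tolist()
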