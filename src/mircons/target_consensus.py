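"""miRNA seed-match detection, multi-predictor consensus and target prioritization.

The detector reports canonical seed sites on a 3'UTR: a *seed match* is the
Watson-Crick reverse complement of miRNA positions 2-7 (6mer core).  The
canonical taxonomy extends the core in two independent directions:

=========  =====================================================
site type  definition on the UTR sense strand (5'->3')
=========  =====================================================
6mer       revcomp of miRNA positions 2-7
7mer-m8    revcomp of miRNA positions 2-8
7mer-A1    6mer core followed by an A opposite miRNA position 1
8mer       revcomp of positions 2-8 followed by the A
=========  =====================================================

Each 6mer-core locus is reported once with the strongest type it supports
(8mer > 7mer-m8 > 7mer-A1 > 6mer).  Coordinates are 0-based half-open on the
UTR sense strand throughout.

Consensus is taken at the gene-miRNA pair level: a pair survives a k-of-n
consensus iff at least k predictors report at least one site for it.  Sites
for surviving pairs are merged per miRNA by interval union, and genes are
prioritized by their total merged site count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import ParameterError, ParseError

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_STRENGTH = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1, "6mer": 0}
SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_DNA = set("ACGTN")
_VALID_MIRNA = set("ACGU")


@dataclass(frozen=True)
class MiRNASeq:
    """A mature miRNA, 5'->3', RNA alphabet; position 1 is the 5' nucleotide."""

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if set(seq) - _VALID_MIRNA:
            raise ParameterError(
                f"miRNA {self.id!r}: invalid characters {sorted(set(seq) - _VALID_MIRNA)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def dna(self) -> str:
        return self.sequence.replace("U", "T")


@dataclass(frozen=True, order=True)
class BindingSite:
    """A located seed-match site, 0-based half-open on the UTR sense strand."""

    gene: str
    mirna: str
    start: int
    end: int
    site_type: str
    predictor: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ParameterError(
                f"site {self.gene}/{self.mirna}: bad interval [{self.start},{self.end})"
            )


@dataclass
class MergedSite:
    """Union of overlapping same-miRNA calls; carries its supporting predictors."""

    gene: str
    mirna: str
    start: int
    end: int
    predictors: set[str] = field(default_factory=set)
    site_types: set[str] = field(default_factory=set)


@dataclass
class ConsensusTarget:
    """A gene with per-miRNA predictor support and merged binding-site counts."""

    gene: str
    support: dict[str, set[str]]          # mirna -> predictor labels
    merged_sites: dict[str, int]          # mirna -> merged site count
    sites: list[MergedSite] = field(default_factory=list)

    @property
    def total_sites(self) -> int:
        return sum(self.merged_sites.values())

    @property
    def n_mirnas(self) -> int:
        return len(self.merged_sites)


def reverse_complement(seq: str) -> str:
    """Reverse complement; U is accepted and normalized to T, N maps to N."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID_DNA
    if bad:
        raise ParameterError(f"invalid nucleotide(s) {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def find_seed_sites(
    mirna: MiRNASeq,
    utr: str,
    site_types: Iterable[str] = SITE_TYPES,
    gene: str = "",
    predictor: str = "seed-match",
) -> list[BindingSite]:
    """Locate every canonical seed-match site of ``mirna`` on ``utr``.

    Each 6mer-core occurrence is reported once, with the strongest requested
    site type the locus supports.  N in the UTR never matches.
    """
    if len(mirna.sequence) < 8:
        raise ParameterError(f"miRNA {mirna.id!r} shorter than 8 nt")
    utr = utr.upper()
    bad = set(utr) - _VALID_DNA
    if bad:
        raise ParameterError(f"UTR contains invalid characters {sorted(bad)}")
    wanted = set(site_types)
    unknown = wanted - set(SITE_TYPES)
    if unknown:
        raise ParameterError(f"unknown site types {sorted(unknown)}")

    m = mirna.dna
    core6 = reverse_complement(m[1:7])          # matches miRNA positions 2-7
    m8_comp = m[7].translate(_COMPLEMENT)       # pairs with miRNA position 8

    sites: list[BindingSite] = []
    i = utr.find(core6)
    while i != -1:
        has_m8 = i >= 1 and utr[i - 1] == m8_comp
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        # strongest supported type that was requested
        if has_m8 and has_a1 and "8mer" in wanted:
            sites.append(BindingSite(gene, mirna.id, i - 1, i + 7, "8mer", predictor))
        elif has_m8 and "7mer-m8" in wanted:
            sites.append(BindingSite(gene, mirna.id, i - 1, i + 6, "7mer-m8", predictor))
        elif has_a1 and "7mer-A1" in wanted:
            sites.append(BindingSite(gene, mirna.id, i, i + 7, "7mer-A1", predictor))
        elif "6mer" in wanted:
            sites.append(BindingSite(gene, mirna.id, i, i + 6, "6mer", predictor))
        i = utr.find(core6, i + 1)
    sites.sort(key=lambda s: (s.start, s.mirna))
    return sites


_PREDICTION_COLUMNS = [
    "predictor", "mirna_id", "gene_id", "utr_start", "utr_end", "site_type", "score",
]


def parse_predictions(path) -> dict[str, list[BindingSite]]:
    """Read predictor site calls from TSV (coordinates 0-based half-open).

    Unknown site types are recorded as ``other``: they participate in
    consensus support and merging but not in the canonical type hierarchy.
    """
    calls: dict[str, list[BindingSite]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                missing = [c for c in _PREDICTION_COLUMNS if c not in header]
                if missing:
                    raise ParseError(f"missing column(s) {missing}", line=lineno)
                idx = {c: header.index(c) for c in _PREDICTION_COLUMNS}
                continue
            try:
                start = int(row[idx["utr_start"]])
                end = int(row[idx["utr_end"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"bad coordinates: {exc}", line=lineno) from exc
            if not 0 <= start < end:
                raise ParseError(f"end <= start ([{start},{end}))", line=lineno)
            stype = row[idx["site_type"]]
            if stype not in SITE_TYPES:
                stype = "other"
            site = BindingSite(
                gene=row[idx["gene_id"]],
                mirna=row[idx["mirna_id"]],
                start=start,
                end=end,
                site_type=stype,
                predictor=row[idx["predictor"]],
            )
            calls.setdefault(site.predictor, []).append(site)
    if header is None:
        raise ParseError("empty file without header")
    return calls


def write_predictions(calls: Mapping[str, Sequence[BindingSite]], path) -> None:
    """Inverse of :func:`parse_predictions` (score column written as 0)."""
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates are 0-based half-open on the UTR sense strand\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PREDICTION_COLUMNS)
        for predictor in sorted(calls):
            for s in sorted(calls[predictor]):
                writer.writerow(
                    [predictor, s.mirna, s.gene, s.start, s.end, s.site_type, 0]
                )


def merge_sites(sites: Sequence[BindingSite]) -> list[MergedSite]:
    """Merge same-miRNA sites on one gene that overlap by >=1 nt.

    Merged intervals span the union of their members; supporting predictors
    are unioned.  Sites of different miRNAs never merge.  Idempotent and
    order-invariant; output sorted by (start, mirna).
    """
    genes = {s.gene for s in sites}
    if len(genes) > 1:
        raise ParameterError(f"merge_sites expects sites of one gene, got {sorted(genes)}")
    merged: list[MergedSite] = []
    by_mirna: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_mirna.setdefault(s.mirna, []).append(s)
    for mirna, group in by_mirna.items():
        group.sort(key=lambda s: (s.start, s.end))
        current: MergedSite | None = None
        for s in group:
            if current is not None and s.start < current.end:
                current.end = max(current.end, s.end)
                current.predictors.add(s.predictor)
                current.site_types.add(s.site_type)
            else:
                current = MergedSite(
                    s.gene, mirna, s.start, s.end, {s.predictor}, {s.site_type}
                )
                merged.append(current)
    merged.sort(key=lambda s: (s.start, s.mirna))
    return merged


def consensus_interactions(
    calls: Mapping[str, Sequence[BindingSite]],
    k: int,
    predictors: Sequence[str] | None = None,
    gene_level: bool = False,
) -> list[ConsensusTarget]:
    """k-of-n consensus over predictor call sets.

    A gene-miRNA pair is retained iff >= ``k`` predictors report >=1 site for
    it (``gene_level=True`` counts predictor support per gene instead).  The
    strict full consensus of n prediction algorithms is ``k = n``; a relaxed
    mode restricts to a named predictor subset via ``predictors``.
    """
    if predictors is not None:
        missing = set(predictors) - set(calls)
        if missing:
            raise ParameterError(f"unknown predictor(s) in whitelist: {sorted(missing)}")
        calls = {p: calls[p] for p in predictors}
    n = len(calls)
    if not 1 <= k <= max(n, 1) or n == 0:
        raise ParameterError(f"k={k} out of range for {n} predictors")

    pair_sites: dict[tuple[str, str], list[BindingSite]] = {}
    pair_support: dict[tuple[str, str], set[str]] = {}
    for predictor, sites in calls.items():
        for s in sites:
            key = (s.gene, s.mirna)
            pair_sites.setdefault(key, []).append(s)
            pair_support.setdefault(key, set()).add(predictor)

    if gene_level:
        gene_support: dict[str, set[str]] = {}
        for (gene, _), preds in pair_support.items():
            gene_support.setdefault(gene, set()).update(preds)
        retained = {key for key in pair_support if len(gene_support[key[0]]) >= k}
    else:
        retained = {key for key, preds in pair_support.items() if len(preds) >= k}

    targets: dict[str, ConsensusTarget] = {}
    for gene, mirna in sorted(retained):
        merged = merge_sites(pair_sites[(gene, mirna)])
        tgt = targets.setdefault(gene, ConsensusTarget(gene, {}, {}, []))
        tgt.support[mirna] = set(pair_support[(gene, mirna)])
        tgt.merged_sites[mirna] = len(merged)
        tgt.sites.extend(merged)
    for tgt in targets.values():
        tgt.sites.sort(key=lambda s: (s.start, s.mirna))
    return [targets[g] for g in sorted(targets)]


class PrioritizedTargets(NamedTuple):
    table: pd.DataFrame     # gene, total_sites, n_mirnas (ranked)
    matrix: pd.DataFrame    # gene x miRNA merged-site counts


def prioritize_targets(
    targets: Sequence[ConsensusTarget],
    min_sites: int = 4,
    by_distinct_mirnas: bool = False,
    exclude: Iterable[str] | None = None,
) -> PrioritizedTargets:
    """Rank genes whose total merged binding sites reach ``min_sites``.

    Default counts total merged sites summed over miRNAs (multiple sites for
    the same miRNA all count); ``by_distinct_mirnas=True`` thresholds on the
    number of distinct supporting miRNAs instead.  Ties break by the other
    count descending, then gene id.  ``exclude`` drops user-specified genes
    (e.g. miRNA-machinery genes) before thresholding.
    """
    if min_sites < 1:
        raise ParameterError("min_sites must be >= 1")
    excluded = {g.casefold() for g in exclude} if exclude else set()
    rows = []
    for t in targets:
        if t.gene.casefold() in excluded:
            continue
        score = t.n_mirnas if by_distinct_mirnas else t.total_sites
        if score >= min_sites:
            rows.append((t.gene, t.total_sites, t.n_mirnas, t.merged_sites))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]) if not by_distinct_mirnas
              else (-r[2], -r[1], r[0]))
    table = pd.DataFrame(
        [(g, ts, nm) for g, ts, nm, _ in rows],
        columns=["gene", "total_sites", "n_mirnas"],
    )
    all_mirnas = sorted({m for _, _, _, ms in rows for m in ms})
    matrix = pd.DataFrame(
        [[ms.get(m, 0) for m in all_mirnas] for _, _, _, ms in rows],
        index=[g for g, _, _, _ in rows],
        columns=all_mirnas,
        dtype=int,
    )
    matrix.index.name = "gene"
    return PrioritizedTargets(table, matrix)
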