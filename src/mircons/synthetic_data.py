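"""Synthetic pipeline inputs with exact ground truth.

Every generator takes one global integer seed and derives independent named
sub-streams from it by stable hashing (CRC32 of the stream label feeds a
``numpy.random.SeedSequence`` together with the seed), so identical seeds are
bit-identical and adding a stream never perturbs the others.

The generators emulate the study conditions of a murine allergic-airway
miRNA profiling experiment:

* two-channel array intensities following the normexp generative model
  (Gaussian background + exponential signal), with a configurable fraction
  of truly differential probes and dedicated control probes;
* qPCR crossing-point tables whose true log2 fold changes invert exactly
  under ddCt (one expression doubling lowers Cp by 1);
* 3'UTR sets with seed-match sites planted at controlled per-gene counts on
  a background scrubbed of accidental matches, so planted counts are exact
  ground truth;
* pseudo-predictors with controllable sensitivity, false-call rate and
  coordinate jitter, standing in for a panel of target-prediction
  algorithms;
* promoters with planted CRE motifs; and
* phenotype vectors (e.g. BAL cell counts, airway resistance) coupled to
  chosen genes' dCp values.

Backgrounds are scrubbed by iterative repair: scan for accidental matches
and mutate one background base inside each offending window until none
remain.  This reaches the same postcondition as rejection sampling (planted
truth is the exact match set) with non-vanishing acceptance probability.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError, PlantingError
from .qpcr_stats import CONTROL, TREATED, CpTable, DcpTable
from .target_consensus import (
    SITE_LENGTH,
    BindingSite,
    MiRNASeq,
    find_seed_sites,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent deterministic RNG stream derived from (seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


# ------------------------------------------------------------------ types ---

@dataclass
class ArraySimulation:
    foreground_red: pd.DataFrame
    foreground_green: pd.DataFrame
    background_red: pd.DataFrame
    background_green: pd.DataFrame
    probe_ids: list[str]
    control_probe_ids: list[str]
    group_labels: pd.Series               # array -> {treated, control}
    truth: pd.DataFrame                   # probe -> true_log2_ratio, is_de
    seed: int


@dataclass
class CpSimulation:
    cp: pd.DataFrame                      # sample x gene
    group_labels: pd.Series
    reference_gene: str
    truth: pd.Series                      # gene -> true log2 fold change
    seed: int

    def to_cp_table(self) -> CpTable:
        return CpTable(self.cp, self.group_labels, self.reference_gene)


@dataclass
class UtrSimulation:
    utr_sequences: dict[str, str]
    mirnas: dict[str, str]                # miRNA id -> RNA sequence
    truth_sites: list[BindingSite]
    seed: int


@dataclass(frozen=True)
class PredictorProfile:
    """Behavioral profile of one pseudo-predictor."""

    name: str
    sensitivity: float = 1.0
    false_calls_per_kb: float = 0.0
    coordinate_jitter: int = 0

    def __post_init__(self):
        if not 0 <= self.sensitivity <= 1:
            raise ParameterError("sensitivity must lie in [0, 1]")
        if self.false_calls_per_kb < 0:
            raise ParameterError("false_calls_per_kb must be >= 0")
        if not 0 <= self.coordinate_jitter <= 3:
            raise ParameterError("coordinate_jitter must lie in [0, 3]")


@dataclass
class PromoterSimulation:
    promoter_sequences: dict[str, str]
    truth_cre: dict[str, list[int]]
    seed: int


@dataclass
class SimTruth:
    """Serializable union of all ground-truth components plus the seed."""

    seed: int
    array_truth: dict = field(default_factory=dict)      # probe -> (log2 ratio, is_de)
    cp_truth: dict = field(default_factory=dict)         # gene -> log2 fc
    utr_sites: list = field(default_factory=list)        # (gene, mirna, start, end, type)
    cre_positions: dict = field(default_factory=dict)    # gene -> [starts]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "array_truth": {k: [float(v[0]), bool(v[1])]
                            for k, v in self.array_truth.items()},
            "cp_truth": {k: float(v) for k, v in self.cp_truth.items()},
            "utr_sites": [list(s) for s in self.utr_sites],
            "cre_positions": {k: [int(p) for p in v]
                              for k, v in self.cre_positions.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimTruth":
        return cls(
            seed=int(d["seed"]),
            array_truth={k: (float(v[0]), bool(v[1]))
                         for k, v in d.get("array_truth", {}).items()},
            cp_truth={k: float(v) for k, v in d.get("cp_truth", {}).items()},
            utr_sites=[tuple(s) for s in d.get("utr_sites", [])],
            cre_positions={k: list(map(int, v))
                           for k, v in d.get("cre_positions", {}).items()},
        )


# ------------------------------------------------------------- two-color ---

def _positive_normal(rng, mean, sd, shape) -> np.ndarray:
    """Normal draws truncated to > 0 by redrawing (negligible for mean >> sd)."""
    out = rng.normal(mean, sd, size=shape)
    for _ in range(100):
        neg = out <= 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, size=int(neg.sum()))
    raise ParameterError("background distribution places too much mass below 0")


def simulate_two_color_array(
    n_probes: int = 580,
    n_arrays: int = 10,
    de_fraction: float = 0.06,
    effect_log2: float = 2.0,
    bg_mean: float = 100.0,
    bg_sd: float = 15.0,
    signal_mean: float = 200.0,
    n_control_probes: int = 4,
    seed: int = 0,
) -> ArraySimulation:
    """Two-channel intensities under the normexp generative model.

    Each spot's foreground is a truncated-Gaussian background draw plus an
    exponential signal draw; the signal draw is made once per spot (a spot
    is one physical feature) and split across the two dyes by the true
    channel ratio, so dye imbalance — not spot abundance — carries the
    effect.  Truly differential probes have their channel
    ratio shifted symmetrically in dye space (red x 2^(+M/2), green
    x 2^(-M/2)) on treated arrays, with M = +-effect_log2 (sign random per
    probe).  The defaults mirror a 580-probe array with n = 5 arrays per
    group.  Control probes (true ratio 0) play the role of a small control
    RNA used for normalization.
    """
    if n_probes <= 0 or n_arrays < 2:
        raise ParameterError("need n_probes >= 1 and n_arrays >= 2")
    if not 0 <= de_fraction <= 1:
        raise ParameterError("de_fraction must lie in [0, 1]")
    if bg_sd <= 0 or signal_mean <= 0 or bg_mean <= 0:
        raise ParameterError("bg_mean, bg_sd and signal_mean must be > 0")
    n_de = round(de_fraction * n_probes)
    if n_de > n_probes - n_control_probes:
        raise ParameterError("de_fraction leaves no room for control probes")

    rng_assign = substream(seed, "array/assign")
    rng_bg = substream(seed, "array/background")
    rng_sig = substream(seed, "array/signal")

    probe_ids = [f"miR-sim-{i + 1:04d}" for i in range(n_probes)]
    control_ids = [f"ctrl-{i + 1:02d}" for i in range(n_control_probes)]
    # controls replace the tail of the probe list so n_probes stays exact
    probe_ids = probe_ids[: n_probes - n_control_probes] + control_ids
    array_ids = [f"array{i + 1:02d}" for i in range(n_arrays)]
    n_treated = n_arrays // 2
    groups = pd.Series(
        [CONTROL] * (n_arrays - n_treated) + [TREATED] * n_treated,
        index=array_ids, name="group",
    )

    candidates = np.arange(n_probes - n_control_probes)
    de_idx = rng_assign.choice(candidates, size=n_de, replace=False)
    log2_ratio = np.zeros(n_probes)
    log2_ratio[de_idx] = effect_log2 * rng_assign.choice([-1.0, 1.0], size=n_de)
    truth = pd.DataFrame(
        {"true_log2_ratio": log2_ratio,
         "is_de": np.isin(np.arange(n_probes), de_idx)},
        index=probe_ids,
    )

    shape = (n_probes, n_arrays)
    treated_mask = (groups == TREATED).to_numpy()[None, :]
    M_true = log2_ratio[:, None] * treated_mask
    # one spot abundance draw per feature, split across dyes by the true ratio
    abundance = rng_sig.exponential(signal_mean, size=shape)
    tables = {}
    for channel, sign in (("red", +0.5), ("green", -0.5)):
        signal = abundance * 2.0 ** (sign * M_true)
        fg = _positive_normal(rng_bg, bg_mean, bg_sd, shape) + signal
        bg = _positive_normal(rng_bg, bg_mean, bg_sd, shape)
        tables[f"foreground_{channel}"] = pd.DataFrame(fg, index=probe_ids,
                                                       columns=array_ids)
        tables[f"background_{channel}"] = pd.DataFrame(bg, index=probe_ids,
                                                       columns=array_ids)
    return ArraySimulation(
        tables["foreground_red"], tables["foreground_green"],
        tables["background_red"], tables["background_green"],
        probe_ids, control_ids, groups, truth, seed,
    )


# ------------------------------------------------------------------- qPCR ---

def simulate_cp_table(
    genes: Sequence[str],
    n_per_group: int = 5,
    true_log2fc: Mapping[str, float] | None = None,
    cp_noise_sd: float = 0.25,
    reference_gene: str = "Hprt",
    seed: int = 0,
) -> CpSimulation:
    """Cp tables whose ddCt analysis inverts the planted log2 fold changes.

    One expression doubling lowers Cp by one cycle, so treated samples of a
    gene with true log2 fold change f have Cp shifted by -f.  The reference
    gene must be present with true fold change 0.  Default n = 5 samples per
    group mirrors a typical small animal-study group size.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    if cp_noise_sd < 0:
        raise ParameterError("cp_noise_sd must be >= 0")
    genes = list(genes)
    if reference_gene not in genes:
        raise ConfigurationError(f"reference gene {reference_gene!r} not in gene list")
    lfc = dict(true_log2fc or {})
    if lfc.get(reference_gene, 0.0) != 0.0:
        raise ConfigurationError("reference gene must have true log2 fold change 0")
    lfc.setdefault(reference_gene, 0.0)
    unknown = set(lfc) - set(genes)
    if unknown:
        raise ConfigurationError(f"true_log2fc for unknown gene(s): {sorted(unknown)}")

    rng = substream(seed, "cp")
    samples = [f"ctrl{i + 1:02d}" for i in range(n_per_group)] + \
              [f"trt{i + 1:02d}" for i in range(n_per_group)]
    groups = pd.Series([CONTROL] * n_per_group + [TREATED] * n_per_group,
                       index=samples, name="group")
    base = pd.Series(rng.uniform(20.0, 30.0, size=len(genes)), index=genes)
    treated = (groups == TREATED).to_numpy()[:, None]
    shift = np.array([lfc.get(g, 0.0) for g in genes])[None, :]
    cp = base.to_numpy()[None, :] - shift * treated
    if cp_noise_sd > 0:
        cp = cp + rng.normal(0.0, cp_noise_sd, size=cp.shape)
    table = pd.DataFrame(cp, index=samples, columns=genes)
    truth = pd.Series({g: lfc.get(g, 0.0) for g in genes}, name="true_log2fc")
    return CpSimulation(table, groups, reference_gene, truth, seed)


# ---------------------------------------------------------- sequence sims ---

def _random_seq(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _place_nonoverlapping(
    rng, lengths: Sequence[int], total: int, spacer: int
) -> list[int]:
    """Random non-overlapping starts with >= spacer nt between consecutive sites."""
    k = len(lengths)
    need = sum(lengths) + spacer * max(k - 1, 0)
    slack = total - need
    if slack < 0:
        raise PlantingError(
            f"cannot place {k} site(s) of total length {sum(lengths)} "
            f"with {spacer}-nt spacers in {total} nt"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    starts = []
    consumed = 0
    for i, length in enumerate(lengths):
        starts.append(int(cuts[i]) + consumed + i * spacer)
        consumed += length
    return starts


def _repair_background(
    rng,
    seq: np.ndarray,
    protected: np.ndarray,
    offending_windows: Callable[[str], list[tuple[int, int]]],
    max_rounds: int = 500,
) -> np.ndarray:
    """Mutate background bases until no accidental match window remains."""
    for _ in range(max_rounds):
        windows = offending_windows("".join(_BASES[seq]))
        if not windows:
            return seq
        progress = False
        for start, end in windows:
            free = [i for i in range(start, end) if not protected[i]]
            if not free:
                continue
            i = int(rng.choice(free))
            seq[i] = (seq[i] + int(rng.integers(1, 4))) % 4
            progress = True
        if not progress:
            break
    raise PlantingError("could not scrub accidental matches from background")


def _site_sequence(mirna_rna: str, site_type: str) -> str:
    m = mirna_rna.replace("U", "T")
    if site_type == "8mer":
        return reverse_complement(m[1:8]) + "A"
    if site_type == "7mer-m8":
        return reverse_complement(m[1:8])
    if site_type == "7mer-A1":
        return reverse_complement(m[1:7]) + "A"
    if site_type == "6mer":
        return reverse_complement(m[1:7])
    raise ParameterError(f"unknown site type {site_type!r}")


def simulate_utr_set(
    n_genes: int,
    utr_length: int,
    mirnas: Mapping[str, str],
    planted_counts: Mapping[str, Mapping[str, int]] | None = None,
    site_type: str = "8mer",
    seed: int = 0,
) -> UtrSimulation:
    """3'UTRs with planted seed-match sites and a scrubbed background.

    ``planted_counts`` maps gene id -> (miRNA id -> site count); its keys
    head the gene list, padded with generated ids up to ``n_genes``.  After
    planting, each UTR is re-scanned and background bases are mutated until
    the detected site set equals the planted truth exactly.
    """
    if n_genes < 1 or utr_length < 20:
        raise ParameterError("need n_genes >= 1 and utr_length >= 20")
    mirna_objs = {mid: MiRNASeq(mid, s) for mid, s in mirnas.items()}
    for mid, m in mirna_objs.items():
        if len(m.sequence) < 8:
            raise ParameterError(f"miRNA {mid!r} must be >= 8 nt")
    planted_counts = {g: dict(c) for g, c in (planted_counts or {}).items()}
    unknown = {m for c in planted_counts.values() for m in c} - set(mirnas)
    if unknown:
        raise ParameterError(f"planted counts reference unknown miRNA(s): {sorted(unknown)}")

    gene_ids = list(planted_counts)
    gene_ids += [f"gene{i + 1:03d}" for i in range(n_genes - len(gene_ids))]
    if len(gene_ids) != n_genes:
        raise ParameterError("more planted genes than n_genes")

    rng = substream(seed, "utr")
    utrs: dict[str, str] = {}
    truth_sites: list[BindingSite] = []
    site_len = SITE_LENGTH[site_type]

    for gene in gene_ids:
        wanted = planted_counts.get(gene, {})
        inserts = [(mid, _site_sequence(mirnas[mid], site_type))
                   for mid, count in sorted(wanted.items()) for _ in range(count)]
        order = rng.permutation(len(inserts))
        inserts = [inserts[i] for i in order]
        starts = _place_nonoverlapping(rng, [site_len] * len(inserts),
                                       utr_length, spacer=2)
        seq = _random_seq(rng, utr_length)
        protected = np.zeros(utr_length, dtype=bool)
        gene_truth = []
        for start, (mid, site_seq) in zip(starts, inserts):
            idx = np.array([_BASES.tolist().index(b) for b in site_seq])
            seq[start:start + site_len] = idx
            protected[start:start + site_len] = True
            gene_truth.append(BindingSite(gene, mid, start, start + site_len,
                                          site_type, "truth"))
        truth_keys = {(s.mirna, s.start, s.end) for s in gene_truth}

        def offending(text: str) -> list[tuple[int, int]]:
            bad = []
            for m in mirna_objs.values():
                for s in find_seed_sites(m, text, gene=gene):
                    if (s.mirna, s.start, s.end) not in truth_keys:
                        bad.append((s.start, s.end))
            return bad

        seq = _repair_background(rng, seq, protected, offending)
        utrs[gene] = "".join(_BASES[seq])
        truth_sites.extend(sorted(gene_truth, key=lambda s: (s.start, s.mirna)))
    return UtrSimulation(utrs, dict(mirnas), truth_sites, seed)


def simulate_predictor_calls(
    truth: UtrSimulation,
    profiles: Sequence[PredictorProfile],
    seed: int = 0,
) -> dict[str, list[BindingSite]]:
    """Per-predictor site tables derived from the truth sites.

    A perfect profile (sensitivity 1, no false calls, no jitter) reproduces
    the truth exactly.  False calls arrive at ``false_calls_per_kb`` per
    predictor per gene, with random miRNA, type and position.
    """
    if not profiles:
        raise ParameterError("need at least one predictor profile")
    mirna_ids = sorted(truth.mirnas)
    calls: dict[str, list[BindingSite]] = {}
    for profile in profiles:
        rng = substream(seed, f"predictor/{profile.name}")
        out: list[BindingSite] = []
        for site in truth.truth_sites:
            if rng.random() >= profile.sensitivity:
                continue
            start, end = site.start, site.end
            if profile.coordinate_jitter:
                j = profile.coordinate_jitter
                length = len(truth.utr_sequences[site.gene])
                start = max(0, start + int(rng.integers(-j, j + 1)))
                end = min(length, end + int(rng.integers(-j, j + 1)))
                if end <= start:
                    end = min(length, start + 1)
            out.append(BindingSite(site.gene, site.mirna, start, end,
                                   site.site_type, profile.name))
        for gene, utr in truth.utr_sequences.items():
            n_fp = rng.poisson(profile.false_calls_per_kb * len(utr) / 1000.0)
            for _ in range(n_fp):
                stype = ("6mer", "7mer-A1", "7mer-m8", "8mer")[int(rng.integers(4))]
                length = SITE_LENGTH[stype]
                start = int(rng.integers(0, max(len(utr) - length, 1)))
                out.append(BindingSite(gene, mirna_ids[int(rng.integers(len(mirna_ids)))],
                                       start, start + length, stype, profile.name))
        out.sort(key=lambda s: (s.gene, s.start, s.mirna))
        calls[profile.name] = out
    return calls


def simulate_promoters(
    n_genes: int,
    length: int = 1100,
    planted: Mapping[str, int] | None = None,
    motif: str = "TGACGTCA",
    seed: int = 0,
) -> PromoterSimulation:
    """Promoters (default 1100 nt, nominally -1000..+100 around a TSS) with
    planted CRE motifs on a background scrubbed of accidental occurrences."""
    if n_genes < 1 or length < len(motif):
        raise ParameterError("need n_genes >= 1 and length >= motif length")
    planted = dict(planted or {})
    gene_ids = list(planted)
    gene_ids += [f"gene{i + 1:03d}" for i in range(n_genes - len(gene_ids))]
    if len(gene_ids) != n_genes:
        raise ParameterError("more planted genes than n_genes")
    motif = motif.upper()
    motif_idx = np.array([_BASES.tolist().index(b) for b in motif])

    rng = substream(seed, "promoter")
    seqs: dict[str, str] = {}
    truth: dict[str, list[int]] = {}
    for gene in gene_ids:
        count = planted.get(gene, 0)
        if len(motif) * count >= length:
            raise PlantingError(f"gene {gene!r}: {count} motifs do not fit in {length} nt")
        starts = _place_nonoverlapping(rng, [len(motif)] * count, length, spacer=2)
        seq = _random_seq(rng, length)
        protected = np.zeros(length, dtype=bool)
        for start in starts:
            seq[start:start + len(motif)] = motif_idx
            protected[start:start + len(motif)] = True
        truth_starts = set(starts)

        def offending(text: str) -> list[tuple[int, int]]:
            bad = []
            i = text.find(motif)
            while i != -1:
                if i not in truth_starts:
                    bad.append((i, i + len(motif)))
                i = text.find(motif, i + 1)
            return bad

        seq = _repair_background(rng, seq, protected, offending)
        seqs[gene] = "".join(_BASES[seq])
        truth[gene] = sorted(starts)
    return PromoterSimulation(seqs, truth, seed)


def simulate_phenotype(
    dcp_table: DcpTable,
    coupled_genes: Sequence[str],
    slope: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Phenotype = slope * mean dCp of the coupled genes + Gaussian noise.

    With noise_sd = 0 the induced Spearman correlation with the coupled dCp
    mean is exactly sign(slope).  Remember the dCp scale: positive slope
    couples the phenotype to *decreasing* expression.
    """
    coupled = list(coupled_genes)
    if not coupled:
        raise ConfigurationError("coupled_genes must be non-empty")
    missing = set(coupled) - set(dcp_table.dcp.columns)
    if missing:
        raise ConfigurationError(f"coupled gene(s) not in dCp table: {sorted(missing)}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = substream(seed, "phenotype")
    base = dcp_table.dcp[coupled].mean(axis=1)
    noise = rng.normal(0.0, noise_sd, size=len(base)) if noise_sd > 0 else 0.0
    return pd.Series(slope * base.to_numpy() + noise, index=base.index,
                     name="phenotype")
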