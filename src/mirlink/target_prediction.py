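"""Canonical seed-site target prediction with duplex refinement.

A mature miRNA recognizes a 3'UTR mainly through its seed, nucleotides
2-8 counted from the miRNA 5' end.  The canonical site types on the UTR
(read 5'->3' on the mRNA sense strand) are:

* ``8mer``     — perfect Watson-Crick match to seed positions 2-8 followed
  by an adenosine opposite miRNA position 1,
* ``7mer-m8``  — match to positions 2-8 only,
* ``7mer-A1``  — match to positions 2-7 followed by the A,
* ``6mer``     — match to positions 2-7 only.

The required ``A`` is an adenosine in the UTR regardless of the actual
miRNA position-1 nucleotide.  Sites are scored with a context-style
surrogate score (site-type baseline plus local AU content and distance
from the UTR ends; more negative = stronger predicted repression) and
optionally refined by a local duplex alignment of the whole miRNA
against the site neighbourhood with wobble-aware scoring.  Predictions
are aggregated per (miRNA, gene) pair and cut at a strength percentile.

Coordinates are 0-based half-open on the UTR sense strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError

_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: site types in decreasing specificity; also the overlap-precedence order
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

#: default context-score coefficients (surrogate values preserving the
#: canonical site-type strength ordering; configurable, not literature fits)
DEFAULT_CONTEXT_PARAMS = {
    "base": {"8mer": -0.31, "7mer-m8": -0.16, "7mer-A1": -0.10, "6mer": -0.02},
    "w_au": 0.20,
    "w_pos": 0.10,
    "cap": 1500,
    "flank": 30,
}

#: duplex alignment column scores: Watson-Crick, G:U wobble, mismatch,
#: gap open (first gap column), gap extend (each further column)
DEFAULT_DUPLEX_PARAMS = {
    "wc": 5,
    "wobble": 2,
    "mismatch": -3,
    "gap_open": -8,
    "gap_extend": -2,
    "seed_multiplier": 2,
}


def normalize_rna(seq: str) -> str:
    """Uppercase and map the DNA alphabet onto RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', RNA alphabet after normalization."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) < 15:
            raise ParameterError(
                f"miRNA {self.id!r} shorter than 15 nt ({len(self.sequence)})"
            )
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ParameterError(f"miRNA {self.id!r} has invalid characters {bad}")

    @property
    def seed(self) -> str:
        """Seed region, miRNA positions 2-8 (1-based)."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR sequence, sense strand 5'->3'; N is allowed and never matches."""

    gene_id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        bad = set(self.sequence) - set("ACGUN")
        if bad:
            raise ParameterError(f"UTR {self.gene_id!r} has invalid characters {bad}")


@dataclass
class SeedSite:
    gene_id: str
    mirna_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    site_type: str
    context_score: float | None = None


@dataclass
class DuplexAlignment:
    mirna_id: str
    gene_id: str
    window_start: int
    window_end: int
    score: float
    aligned_pair: str


@dataclass
class TargetPrediction:
    mirna_id: str
    gene_id: str
    sites: list[SeedSite]
    aggregate_score: float
    percentile_rank: float
    refined: bool | None = None
    retained: bool = True
    best_duplex_score: float | None = None


def site_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """UTR match strings for the four canonical site types of one miRNA.

    With rc() the reverse complement: 7mer-m8 = rc(pos 2-8);
    8mer = rc(pos 2-8) + "A"; 7mer-A1 = rc(pos 2-7) + "A"; 6mer = rc(pos 2-7).
    """
    if len(mirna.sequence) < 8:
        raise ParameterError(f"miRNA {mirna.id!r} shorter than 8 nt")
    m8 = reverse_complement(mirna.sequence[1:8])
    a1 = reverse_complement(mirna.sequence[1:7])
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": a1 + "A", "6mer": a1}


def scan_sites(mirna: MatureMiRNA, utr: UTRRecord) -> list[SeedSite]:
    """All canonical seed sites of ``mirna`` in ``utr``.

    Overlapping windows are resolved greedily by type precedence
    8mer > 7mer-m8 > 7mer-A1 > 6mer, so each window is reported once as
    its most specific type (the 7mer contained in every 8mer window is
    not reported separately).  Output is sorted by start, then precedence.
    """
    seq = utr.sequence
    patterns = site_patterns(mirna)
    accepted: list[tuple[int, int, str]] = []
    for stype in SITE_TYPES:
        pat = patterns[stype]
        n = len(pat)
        pos = seq.find(pat)
        while pos != -1:
            end = pos + n
            if not any(pos < a_end and a_start < end for a_start, a_end, _ in accepted):
                accepted.append((pos, end, stype))
            pos = seq.find(pat, pos + 1)
    rank = {t: i for i, t in enumerate(SITE_TYPES)}
    accepted.sort(key=lambda s: (s[0], rank[s[2]]))
    return [SeedSite(utr.gene_id, mirna.id, s, e, t) for s, e, t in accepted]


def context_score(
    site: SeedSite, utr: UTRRecord, params: dict | None = None
) -> float:
    """Context-style site score; more negative = stronger.

    score = base(type) + w_au * (0.5 - AU fraction of up-to-``flank``-nt
    flanks on each side) + w_pos * min(d_end, cap) / cap, where d_end is
    the distance from the site midpoint to the nearer UTR end.
    """
    p = {**DEFAULT_CONTEXT_PARAMS, **(params or {})}
    seq = utr.sequence
    if not (0 <= site.start < site.end <= len(seq)):
        raise ParameterError(
            f"site [{site.start},{site.end}) outside UTR {utr.gene_id!r}"
        )
    fl = p["flank"]
    flanks = seq[max(0, site.start - fl) : site.start] + seq[site.end : site.end + fl]
    au = sum(1 for b in flanks if b in "AU") / len(flanks) if flanks else 0.5
    mid = (site.start + site.end) / 2
    d_end = min(mid, len(seq) - mid)
    return (
        p["base"][site.site_type]
        + p["w_au"] * (0.5 - au)
        + p["w_pos"] * min(d_end, p["cap"]) / p["cap"]
    )


def _pair_score(mirna_base: str, utr_base: str, params: dict) -> float | None:
    """Column score for pairing one miRNA base with one UTR base."""
    if _RC.get(mirna_base) == utr_base:
        return params["wc"]
    if (mirna_base, utr_base) in (("G", "U"), ("U", "G")):
        return params["wobble"]
    return params["mismatch"]


def duplex_align(
    mirna: MatureMiRNA,
    utr: UTRRecord,
    site: SeedSite,
    extension: int = 25,
    params: dict | None = None,
) -> DuplexAlignment:
    """Best local alignment of the reversed miRNA against the site window.

    The UTR window is [site.start - extension, site.end + extension),
    clipped at the UTR bounds.  The miRNA is reversed so both strands
    read in the same direction; aligned-column scores (Watson-Crick +5,
    G:U wobble +2, mismatch -3) are doubled when the column pairs a
    miRNA seed position (2-8).  Gaps: open -8, each further column -2,
    never doubled.  Empty alignment scores 0 (local floor).
    """
    p = {**DEFAULT_DUPLEX_PARAMS, **(params or {})}
    w_start = max(0, site.start - extension)
    w_end = min(len(utr.sequence), site.end + extension)
    window = utr.sequence[w_start:w_end]
    m = mirna.sequence[::-1]  # reversed: index i is miRNA position len-i (1-based)
    L = len(mirna.sequence)
    seed_flags = [2 <= L - i <= 8 for i in range(len(m))]
    best, best_ij = local_affine_align(m, window, seed_flags, p)

    aligned = ""
    if best_ij is not None:
        aligned = f"{m[best_ij[0]-1]}|{window[best_ij[1]-1]}"
    return DuplexAlignment(mirna.id, utr.gene_id, w_start, w_end, float(best), aligned)


def local_affine_align(
    m: str, window: str, seed_flags: list[bool], p: dict
) -> tuple[float, tuple[int, int] | None]:
    """Gotoh local alignment of ``m`` against ``window``.

    ``seed_flags[i]`` doubles the column score when ``m[i]`` is a seed
    position.  Gap open is the first gap column's cost, gap extend each
    further column's; gap columns are never doubled.  Returns the best
    score (>= 0, empty alignment floor) and its DP end cell.
    """
    n, w = len(m), len(window)
    NEG = float("-inf")
    M = np.full((n + 1, w + 1), NEG)
    Ix = np.full((n + 1, w + 1), NEG)  # gap in window (consumes m)
    Iy = np.full((n + 1, w + 1), NEG)  # gap in m (consumes window)
    M[0, :] = 0.0
    M[:, 0] = 0.0
    best = 0.0
    best_ij = None
    for i in range(1, n + 1):
        for j in range(1, w + 1):
            s = _pair_score(m[i - 1], window[j - 1], p)
            if seed_flags[i - 1]:
                s *= p["seed_multiplier"]
            diag = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1], 0.0)
            M[i, j] = diag + s
            Ix[i, j] = max(
                max(M[i - 1, j], Iy[i - 1, j]) + p["gap_open"],
                Ix[i - 1, j] + p["gap_extend"],
            )
            Iy[i, j] = max(
                max(M[i, j - 1], Ix[i, j - 1]) + p["gap_open"],
                Iy[i, j - 1] + p["gap_extend"],
            )
            if M[i, j] > best:
                best = M[i, j]
                best_ij = (i, j)
    return float(best), best_ij


def aggregate_and_rank(
    sites_by_pair: dict[tuple[str, str], list[SeedSite]],
    duplexes: dict[tuple[str, str], float] | None = None,
    percentile: float = 95.0,
    duplex_threshold: float = 80.0,
    refine: bool = False,
    include_6mer: bool = False,
    per_mirna: bool = False,
) -> list[TargetPrediction]:
    """Aggregate site scores per (miRNA, gene) pair and cut at a percentile.

    aggregate_score is the sum of the pair's site context scores (6mer
    sites excluded unless ``include_6mer``); targeting strength is its
    negation.  A pair is retained iff its strength is at or beyond the
    ``percentile``-th percentile of all pairs' strengths (ties at the
    cut retained), globally by default or within each miRNA when
    ``per_mirna``.  ``refined`` is set iff the pair's best duplex score
    is >= ``duplex_threshold``; with ``refine`` both filters apply
    conjunctively.  Output: retained predictions sorted by strength
    (strongest first), then (miRNA, gene).
    """
    if not 0 < percentile < 100:
        raise ParameterError(f"percentile must be in (0, 100), got {percentile}")
    if not sites_by_pair:
        return []
    pairs = sorted(sites_by_pair)
    aggregates = {}
    for pair in pairs:
        sites = sites_by_pair[pair]
        if not sites:
            raise ParameterError(f"pair {pair} has an empty site list")
        scored = [
            s for s in sites if include_6mer or s.site_type != "6mer"
        ]
        if any(s.context_score is None for s in scored):
            raise ParameterError(f"pair {pair} has unscored sites")
        aggregates[pair] = sum(s.context_score for s in scored)
    strengths = {pair: -aggregates[pair] for pair in pairs}

    def _cut(values: np.ndarray) -> float:
        return float(np.percentile(values, percentile))

    if per_mirna:
        cutoffs = {}
        for mirna_id in {m for m, _ in pairs}:
            vals = np.array([strengths[p] for p in pairs if p[0] == mirna_id])
            cutoffs[mirna_id] = _cut(vals)
        retained = {p: strengths[p] >= cutoffs[p[0]] for p in pairs}
    else:
        all_vals = np.array([strengths[p] for p in pairs])
        cutoff = _cut(all_vals)
        retained = {p: strengths[p] >= cutoff for p in pairs}

    global_vals = np.array([strengths[p] for p in pairs])
    predictions = []
    for pair in pairs:
        mirna_id, gene_id = pair
        best_duplex = duplexes.get(pair) if duplexes is not None else None
        refined = None
        if best_duplex is not None:
            refined = best_duplex >= duplex_threshold
        keep = retained[pair]
        if refine:
            keep = keep and bool(refined)
        predictions.append(
            TargetPrediction(
                mirna_id=mirna_id,
                gene_id=gene_id,
                sites=sites_by_pair[pair],
                aggregate_score=aggregates[pair],
                percentile_rank=float(
                    stats.percentileofscore(global_vals, strengths[pair], kind="weak")
                ),
                refined=refined,
                retained=keep,
                best_duplex_score=best_duplex,
            )
        )
    predictions.sort(key=lambda p: (p.aggregate_score, p.mirna_id, p.gene_id))
    return [p for p in predictions if p.retained]
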