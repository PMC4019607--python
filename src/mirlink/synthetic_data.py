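"""Synthetic bone-marrow culture time-course datasets with planted truth.

Emulates the study design the pipeline assumes: one uncultured-control
condition plus six culture timepoints sampled every second day (d4-d14),
three independent cultures, a panel of miRNAs of which a chosen subset
is planted up- or down-regulated at >= 5-fold, 3'UTRs carrying planted
canonical seed sites, gene trajectories planted anti-correlated with
their regulating miRNA, and an annotation/pathway collection with one
planted enriched pathway.  Every generator is deterministic under the
configured seed (byte-identical outputs) and every planted element is
recorded in a ground-truth sidecar, so each downstream stage can be
checked for exact recovery.

Noise model: multiplicative log-normal — each replicate value is the
noise-free expectation times exp(N(0, noise_sigma^2)) — because
fluorescence intensities are positive and right-skewed.  Planted
trajectories ramp log-linearly from the control baseline to
baseline x fold at the final timepoint (the simplest monotone shape
satisfying the endpoint fold contract).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_filter import DEFAULT_TERMS
from .errors import ParameterError, PlacementError
from .seqio import write_fasta, write_gmt
from .target_prediction import (
    SITE_LENGTH,
    SITE_TYPES,
    MatureMiRNA,
    UTRRecord,
    site_patterns,
)

DEFAULT_TIMEPOINTS = ("control", "d4", "d6", "d8", "d10", "d12", "d14")

# stage tags appended to the seed sequence so each generator draws an
# independent, call-order-insensitive stream
_STAGE = {"mirnas": 1, "utrs": 2, "expression": 3, "trajectories": 4, "genesets": 5}


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic dataset."""

    rng_seed: int = 0
    n_mirna: int = 20
    n_genes: int = 60
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    planted_up: tuple[tuple[str, float], ...] = ()
    planted_down: tuple[tuple[str, float], ...] = ()
    noise_sigma: float = 0.2
    utr_length: int = 1000
    planted_sites: tuple[tuple[str, str, str], ...] = ()  # (mirna, gene, type)
    planted_links: tuple[tuple[str, str, int, float], ...] = ()  # (mirna, gene, sign, strength)
    trajectory_noise_sigma: float = 0.1
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (10, 40)
    enriched_pathway_overlap: int = 5
    annotated_fraction: float = 0.3
    clean_background: bool = True
    clean_6mer: bool = False  # also scrub background 6mer sites (may not converge)
    mirna_length: int = 22

    def __post_init__(self):
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ParameterError("timepoints must be unique")
        if len(self.timepoints) < 2:
            raise ParameterError("need a control plus >= 1 culture timepoint")
        if self.noise_sigma < 0 or self.trajectory_noise_sigma < 0:
            raise ParameterError("noise sigma must be >= 0")
        up_ids = {m for m, _ in self.planted_up}
        down_ids = {m for m, _ in self.planted_down}
        if up_ids & down_ids:
            raise ParameterError(f"miRNAs planted both up and down: {up_ids & down_ids}")
        for mid, fold in self.planted_up:
            if not fold >= 1:
                raise ParameterError(f"up fold for {mid} must be >= 1, got {fold}")
        for mid, fold in self.planted_down:
            if not 0 < fold <= 1:
                raise ParameterError(f"down fold for {mid} must be in (0, 1], got {fold}")
        for mid, gid, stype in self.planted_sites:
            if stype not in SITE_TYPES:
                raise ParameterError(f"unknown site type {stype!r} for ({mid}, {gid})")
        for mid, gid, sign, strength in self.planted_links:
            if sign not in (-1, 1):
                raise ParameterError(f"link sign must be +-1, got {sign}")
            if not 0 < strength <= 1:
                raise ParameterError(
                    f"link strength must be in (0, 1], got {strength} for ({mid}, {gid})"
                )

    @property
    def control(self) -> str:
        return self.timepoints[0]

    @property
    def culture_timepoints(self) -> tuple[str, ...]:
        return self.timepoints[1:]

    def mirna_ids(self) -> list[str]:
        return [f"mir-{i + 1:03d}" for i in range(self.n_mirna)]

    def gene_ids(self) -> list[str]:
        return [f"gene-{i + 1:03d}" for i in range(self.n_genes)]

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, _STAGE[stage]])


@dataclass
class GroundTruth:
    """Planted truth recorded alongside every simulated dataset."""

    differential_up: list[str] = field(default_factory=list)
    differential_down: list[str] = field(default_factory=list)
    true_sites: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    true_links: list[tuple[str, str, int]] = field(default_factory=list)
    enriched_pathway: str | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            differential_up=raw["differential_up"],
            differential_down=raw["differential_down"],
            true_sites=[tuple(s) for s in raw["true_sites"]],
            true_links=[tuple(l) for l in raw["true_links"]],
            enriched_pathway=raw.get("enriched_pathway"),
        )


def default_config(rng_seed: int = 0, **overrides) -> SimulationConfig:
    """A ready-to-run scenario: 3 up / 4 down planted miRNAs at 8-fold /
    0.125-fold among nulls, each with an 8mer plus a 7mer-m8 site in its
    target 3'UTR and a planted anti-correlated target trajectory.

    The gene panel (150 random-background UTRs) is sized so the
    95th-percentile strength cut operates on a populated pair
    distribution with the planted two-site pairs near the top, as in a
    transcriptome-scale scan.
    """
    planted_up = tuple((f"mir-{i:03d}", 8.0) for i in (1, 2, 3))
    planted_down = tuple((f"mir-{i:03d}", 0.125) for i in (4, 5, 6, 7))
    pairs = [(f"mir-{i:03d}", f"gene-{i:03d}") for i in range(1, 8)]
    sites = []
    for m, g in pairs:
        sites.append((m, g, "8mer"))
        sites.append((m, g, "7mer-m8"))
    base = dict(
        rng_seed=rng_seed,
        n_genes=150,
        clean_background=False,
        planted_up=planted_up,
        planted_down=planted_down,
        planted_sites=tuple(sites),
        planted_links=tuple((m, g, -1, 1.0) for m, g in pairs),
    )
    base.update(overrides)
    return SimulationConfig(**base)


def study_design_config(rng_seed: int = 0, n_null: int = 232) -> SimulationConfig:
    """Emulate the deposited array design at headline scale: 26 planted
    up- and 42 planted down-regulated miRNAs (folds >= 5 in magnitude)
    among ``n_null`` unchanged miRNAs, 3 cultures, control + d4..d14.

    Only the expression arm is planted; no sites or links, so this
    config exercises normalization and selection at realistic size.
    """
    rng = np.random.default_rng([rng_seed, 99])
    n_mirna = 26 + 42 + n_null
    ids = [f"mir-{i + 1:03d}" for i in range(n_mirna)]
    up_folds = 8.0 * 2.0 ** rng.uniform(0.0, 3.0, size=26)
    down_folds = 1.0 / (8.0 * 2.0 ** rng.uniform(0.0, 3.0, size=42))
    return SimulationConfig(
        rng_seed=rng_seed,
        n_mirna=n_mirna,
        n_genes=1,
        planted_up=tuple(zip(ids[:26], up_folds)),
        planted_down=tuple(zip(ids[26:68], down_folds)),
        planted_sites=(),
        planted_links=(),
    )


def gen_mirnas(config: SimulationConfig) -> list[tuple[str, str]]:
    """Random mature miRNA records (unique id, 22-nt sequence over ACGU)."""
    if config.n_mirna < 1:
        raise ParameterError("n_mirna must be >= 1")
    rng = config.rng("mirnas")
    bases = np.array(list("ACGU"))
    return [
        (mid, "".join(rng.choice(bases, size=config.mirna_length)))
        for mid in config.mirna_ids()
    ]


def _background_patterns(mirnas: list[tuple[str, str]], clean_6mer: bool) -> list[str]:
    """Site patterns that must not appear in a clean background."""
    kinds = SITE_TYPES if clean_6mer else ("8mer", "7mer-m8", "7mer-A1")
    patterns = []
    for mid, seq in mirnas:
        pats = site_patterns(MatureMiRNA(mid, seq))
        patterns.extend(pats[k] for k in kinds)
    return sorted(set(patterns))


def gen_utrs_with_sites(
    config: SimulationConfig, mirnas: list[tuple[str, str]]
) -> tuple[list[tuple[str, str]], list[tuple[str, str, int, int, str]]]:
    """Random 3'UTRs with the configured seed sites planted.

    Each planted (miRNA, gene, type) gets exactly its site string at a
    recorded non-overlapping position.  With ``clean_background`` the
    rest of every UTR is rejection-sampled (by point mutation outside
    planted windows) until no unplanted 7/8-mer site of any simulated
    miRNA remains (6mers too when ``clean_6mer``).
    """
    if config.utr_length < 50:
        raise ParameterError("utr_length must be >= 50")
    mirna_map = dict(mirnas)
    for mid, gid, _ in config.planted_sites:
        if mid not in mirna_map:
            raise ParameterError(f"planted site references unknown miRNA {mid!r}")
        if gid not in config.gene_ids():
            raise ParameterError(f"planted site references unknown gene {gid!r}")

    rng = config.rng("utrs")
    bases = np.array(list("ACGU"))
    clean_pats = (
        _background_patterns(mirnas, config.clean_6mer)
        if config.clean_background
        else []
    )
    # planted-target UTRs never carry chance sites of other planted miRNAs:
    # otherwise a planted regulator could appear to target someone else's
    # gene, confounding link recovery
    planted_mirna_ids = (
        {m for m, _ in config.planted_up}
        | {m for m, _ in config.planted_down}
        | {m for m, _, _ in config.planted_sites}
    )
    planted_gene_pats = _background_patterns(
        [(m, s) for m, s in mirnas if m in planted_mirna_ids], config.clean_6mer
    )
    planted_gene_ids = {g for _, g, _ in config.planted_sites} | {
        g for _, g, _, _ in config.planted_links
    }

    utrs: list[tuple[str, str]] = []
    truth_sites: list[tuple[str, str, int, int, str]] = []
    for gid in config.gene_ids():
        planted = [(m, t) for m, g, t in config.planted_sites if g == gid]
        seq = rng.choice(bases, size=config.utr_length)
        windows: list[tuple[int, int]] = []
        for mid, stype in planted:
            pats = site_patterns(MatureMiRNA(mid, mirna_map[mid]))
            pattern = pats[stype]
            length = SITE_LENGTH[stype]
            placed = False
            for _ in range(200):
                start = int(rng.integers(10, config.utr_length - length - 10))
                end = start + length
                # one-base buffer keeps the type-guard context positions free
                if all(end + 1 <= ws or we + 1 <= start for ws, we in windows):
                    seq[start:end] = list(pattern)
                    # pin the flanking context so the planted window scans as
                    # exactly its planted type (no chance upgrade to a more
                    # specific overlapping type)
                    if stype in ("7mer-m8", "6mer") and seq[end] == "A":
                        seq[end] = str(rng.choice(["C", "G", "U"]))
                    if stype in ("7mer-A1", "6mer"):
                        c8 = pats["7mer-m8"][0]
                        if seq[start - 1] == c8:
                            seq[start - 1] = str(
                                rng.choice([b for b in "ACGU" if b != c8])
                            )
                    windows.append((start, end))
                    truth_sites.append((mid, gid, start, end, stype))
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place {stype} site for ({mid}, {gid}) without overlap"
                )
        pats_to_scrub = clean_pats if clean_pats else (
            planted_gene_pats if gid in planted_gene_ids else []
        )
        if pats_to_scrub:
            seq = _scrub_background(seq, windows, pats_to_scrub, rng, gid)
        utrs.append((gid, "".join(seq)))
    return utrs, truth_sites


def _scrub_background(
    seq: np.ndarray,
    windows: list[tuple[int, int]],
    patterns: list[str],
    rng: np.random.Generator,
    gene_id: str,
    max_rounds: int = 300,
) -> np.ndarray:
    """Point-mutate the background until no listed pattern occurs outside
    the planted windows."""
    text = "".join(seq)
    for _ in range(max_rounds):
        violation = None
        for pat in patterns:
            pos = text.find(pat)
            while pos != -1:
                span = (pos, pos + len(pat))
                if not any(ws <= span[0] and span[1] <= we for ws, we in windows):
                    violation = span
                    break
                pos = text.find(pat, pos + 1)
            if violation:
                break
        if violation is None:
            return np.array(list(text))
        # mutate one background position inside the offending occurrence
        candidates = [
            i
            for i in range(*violation)
            if not any(ws <= i < we for ws, we in windows)
        ]
        if not candidates:
            raise PlacementError(
                f"spurious site inside planted windows of {gene_id!r}; cannot scrub"
            )
        i = int(rng.choice(candidates))
        alternatives = [b for b in "ACGU" if b != text[i]]
        text = text[:i] + str(rng.choice(alternatives)) + text[i + 1 :]
    raise PlacementError(f"background of {gene_id!r} could not be cleaned")


def gen_expression_timecourse(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """miRNA expression matrix over control + culture timepoints.

    Per-miRNA control baseline b is log-uniform in [50, 5000]
    fluorescence units; a miRNA planted at fold f ramps log-linearly to
    b*f at the final timepoint; non-planted miRNAs stay flat.  Each
    replicate value is the expectation times exp(N(0, noise_sigma^2)).
    """
    if config.noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    rng = config.rng("expression")
    folds = dict(config.planted_up) | dict(config.planted_down)
    tps = config.culture_timepoints
    T = len(tps)
    columns = [
        f"{tp}_r{r + 1}" for tp in config.timepoints for r in range(config.n_replicates)
    ]
    rows = {}
    for mid in config.mirna_ids():
        baseline = 10.0 ** rng.uniform(np.log10(50.0), np.log10(5000.0))
        fold = folds.get(mid, 1.0)
        expected = {config.control: baseline}
        for j, tp in enumerate(tps, start=1):
            expected[tp] = baseline * fold ** (j / T)
        values = []
        for tp in config.timepoints:
            noise = rng.normal(0.0, config.noise_sigma, size=config.n_replicates)
            values.extend(expected[tp] * np.exp(noise))
        rows[mid] = values
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    matrix.index.name = "mirna"
    truth = GroundTruth(
        differential_up=sorted(m for m, _ in config.planted_up),
        differential_down=sorted(m for m, _ in config.planted_down),
    )
    return matrix, truth


def gen_target_trajectories(
    config: SimulationConfig, expression: pd.DataFrame
) -> pd.DataFrame:
    """Gene trajectories on the culture-timepoint grid.

    A gene planted in a link of sign s and strength w follows
    s * w * (standardized miRNA log2 trajectory) in log2 space, plus
    i.i.d. N(0, trajectory_noise_sigma) noise; unlinked genes are pure
    noise around a flat baseline.  Values are positive (100 * 2^log).
    """
    rng = config.rng("trajectories")
    tps = list(config.culture_timepoints)
    # timepoint means of the miRNA matrix, log2 fold vs control
    mean_by_tp = {}
    for tp in config.timepoints:
        cols = [c for c in expression.columns if c.rsplit("_", 1)[0] == tp]
        mean_by_tp[tp] = expression[cols].mean(axis=1)
    log2fc = pd.DataFrame(
        {tp: np.log2(mean_by_tp[tp] / mean_by_tp[config.control]) for tp in tps}
    )

    links = {(m, g): (s, w) for m, g, s, w in config.planted_links}
    for (mid, gid) in links:
        if mid not in expression.index:
            raise ParameterError(f"planted link references unknown miRNA {mid!r}")
        if gid not in config.gene_ids():
            raise ParameterError(f"planted link references unknown gene {gid!r}")

    rows = {}
    for gid in config.gene_ids():
        linked = [(m, s, w) for (m, g), (s, w) in links.items() if g == gid]
        noise = rng.normal(0.0, config.trajectory_noise_sigma, size=len(tps))
        if linked:
            mid, sign, strength = linked[0]
            traj = log2fc.loc[mid].to_numpy()
            sd = traj.std()
            if sd == 0:
                raise ParameterError(
                    f"miRNA {mid!r} trajectory is flat; cannot standardize for {gid!r}"
                )
            z = (traj - traj.mean()) / sd
            logvals = sign * strength * z + noise
        else:
            logvals = noise
        rows[gid] = 100.0 * np.power(2.0, logvals)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=tps)
    table.index.name = "gene"
    return table


def gen_genesets(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, set[str]], str]:
    """Annotation map and pathway collection with one planted enrichment.

    The designated first pathway receives ``enriched_pathway_overlap``
    genes from the planted target-gene query set; other memberships are
    random.  Query-term annotations (evidence >= 1) go to a fraction of
    genes, planted target genes first, so the term filter keeps exactly
    the planted genes when the fraction covers them and nothing when it
    is zero.  Returns (annotation long table, pathways, enriched id).
    """
    if config.n_pathways < 1:
        raise ParameterError("n_pathways must be >= 1")
    rng = config.rng("genesets")
    genes = config.gene_ids()
    query_set = sorted({g for _, g, _ in config.planted_sites})

    lo, hi = config.pathway_size_range
    pathways: dict[str, set[str]] = {}
    enriched_id = "path-01"
    for i in range(config.n_pathways):
        name = f"path-{i + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        if name == enriched_id:
            k = config.enriched_pathway_overlap
            if k > min(size, len(query_set)) and k > 0:
                if k > size:
                    raise ParameterError(
                        f"enriched overlap {k} exceeds pathway size {size}"
                    )
                raise ParameterError(
                    f"enriched overlap {k} exceeds query-set size {len(query_set)}"
                )
            members = set(query_set[:k])
            # fill from non-query genes so the planted overlap is exactly k
            pool = [g for g in genes if g not in query_set]
            members |= set(rng.choice(pool, size=size - k, replace=False))
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        pathways[name] = members

    n_annotated = int(round(config.annotated_fraction * len(genes)))
    ordered = query_set + [g for g in genes if g not in query_set]
    annotated = ordered[:n_annotated]
    terms = list(DEFAULT_TERMS)
    records = []
    for g in annotated:
        term = terms[int(rng.integers(0, len(terms)))]
        records.append((g, term, int(rng.integers(1, 6))))
    # decoy annotations that must never pass the exact-term filter
    for g in genes:
        if rng.random() < 0.2:
            records.append((g, f"unrelated-term-{int(rng.integers(1, 9))}", 3))
    annotation = pd.DataFrame(records, columns=["gene", "term", "evidence_count"])
    annotation = annotation.sort_values(["gene", "term"], kind="stable").reset_index(
        drop=True
    )
    return annotation, pathways, enriched_id


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input plus the ground-truth sidecar.

    Writes miRNA/UTR FASTA, expression and trajectory TSVs, annotation
    TSV, pathway GMT and truth JSON; byte-identical under a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirnas = gen_mirnas(config)
    utrs, true_sites = gen_utrs_with_sites(config, mirnas)
    expression, truth = gen_expression_timecourse(config)
    trajectories = gen_target_trajectories(config, expression)
    annotation, pathways, enriched_id = gen_genesets(config)
    truth.true_sites = true_sites
    truth.true_links = [(m, g, s) for m, g, s, _ in config.planted_links]
    truth.enriched_pathway = enriched_id

    paths = {
        "mirnas": outdir / "mirnas.fasta",
        "utrs": outdir / "utrs.fasta",
        "expression": outdir / "expression.tsv",
        "trajectories": outdir / "trajectories.tsv",
        "annotation": outdir / "annotation.tsv",
        "pathways": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    write_fasta(mirnas, paths["mirnas"])
    write_fasta(utrs, paths["utrs"])
    expression.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    trajectories.to_csv(paths["trajectories"], sep="\t", float_format="%.6f")
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    write_gmt(pathways, paths["pathways"])
    truth.to_json(paths["truth"])
    return paths
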