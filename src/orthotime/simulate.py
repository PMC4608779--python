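"""Synthetic two-species time-course experiments with known ground truth.

The generator emulates the structure of a paired human/mouse embryonic stem
cell differentiation study: human cultures profiled at days 0, 3, ..., 21
and mouse at days 0-7 and 10, three replicates per time point, on two
unrelated microarray platforms (several probes per gene, probe-specific
offsets).  Genes belong to co-expressed clusters whose shapes are piecewise
linear in *mouse developmental time*; the human time axis is related to the
mouse axis by a multiplicative dilation (default 2.1 = 21/10, mirroring the
roughly two-fold difference in population doubling time between the two
cell types).  Clusters are either conserved (same shape in both species) or
divergent (a different template in human).

A matching promoter/motif layer plants position-weight-matrix occurrences
in the promoters of chosen clusters so that motif-enrichment stages can be
validated against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BASES, GroundTruth, MotifLibrary, PWM, TimeCourseMatrix

HUMAN_DAYS = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
MOUSE_DAYS = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 10.0)

#: shape templates; "peak:d" places a triangular bump centered at mouse day d.
#: The default set is chosen to be well separated in correlation space
#: (pairwise |PCC| of standardized templates <= 0.49); the trailing "flat"
#: cluster models non-regulated (background) genes.
DEFAULT_SHAPES = ("down", "up", "peak:2", "peak:5", "peak:8", "flat")

PEAK_HALF_WIDTH = 2.0  # mouse days


@dataclass
class SimConfig:
    """Parameters of a simulated two-species experiment.

    Noise and amplitudes are in log2 expression units.  ``time_dilation``
    maps human days onto the mouse clock: a human day ``t`` corresponds to
    mouse time ``t / time_dilation``.  ``presence_absent_fraction`` is the
    per-species probability that a gene is silent (low flat signal, "A"
    detection calls).
    """

    n_genes: int = 2000
    n_clusters: int = 6
    cluster_shapes: tuple[str, ...] = DEFAULT_SHAPES
    conserved_fraction: float = 0.7
    time_dilation: float = 2.1
    probes_per_gene_mean: float = 2.5
    probes_per_gene_max: int = 5
    n_replicates: int = 3
    noise_sd: float = 0.2
    amplitude: float = 2.0
    #: SD (log2 units) of the smooth per-gene deviation from the cluster
    #: template -- biological within-cluster heterogeneity.  Shared across
    #: species for genes of conserved clusters; drawn independently for
    #: the human side of divergent clusters.
    gene_shape_jitter: float = 0.2
    baseline: float = 8.0
    silent_baseline: float = 4.0
    probe_offset_sd: float = 0.5
    human_days: tuple[float, ...] = HUMAN_DAYS
    mouse_days: tuple[float, ...] = MOUSE_DAYS
    presence_absent_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for grid in (self.human_days, self.mouse_days):
            if grid[0] != 0 or any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError("day grids must be strictly increasing from 0")
        for frac in (self.conserved_fraction, self.presence_absent_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.time_dilation <= 0:
            raise ValueError("time_dilation must be positive")
        if self.n_clusters > self.n_genes:
            raise ValueError("n_clusters may not exceed n_genes")
        if self.n_clusters < 1 or self.n_genes < 1:
            raise ValueError("need at least one gene and one cluster")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# shape templates
# ---------------------------------------------------------------------------

def shape_value(name: str, s: np.ndarray, s_max: float) -> np.ndarray:
    """Evaluate a template at mouse-time ``s`` (clamped to [0, s_max]).

    Templates are piecewise linear with range [-1, 1]:

    * ``down`` -- linear decrease from +1 to -1;
    * ``delayed_down`` -- flat at +1 until s_max / 2, then down to -1;
    * ``peak:d`` -- triangular bump centered at day ``d`` (half-width
      :data:`PEAK_HALF_WIDTH`), baseline 0;
    * ``up`` -- linear increase from -1 to +1;
    * ``flat`` -- constant 0.
    """
    s = np.clip(np.asarray(s, dtype=float), 0.0, s_max)
    if name == "down":
        return 1.0 - 2.0 * s / s_max
    if name == "delayed_down":
        half = s_max / 2.0
        return np.where(s < half, 1.0, 1.0 - 2.0 * (s - half) / (s_max - half))
    if name == "up":
        return -1.0 + 2.0 * s / s_max
    if name == "flat":
        return np.zeros_like(s)
    if name.startswith("peak:"):
        center = float(name.split(":", 1)[1])
        return np.clip(1.0 - np.abs(s - center) / PEAK_HALF_WIDTH, 0.0, None)
    raise ValueError(f"unknown shape template {name!r}")


def _species_shape(cfg: SimConfig, species: str, cluster: int,
                   conserved: np.ndarray) -> str:
    """Template used by ``cluster`` in ``species``.

    Conserved clusters reuse the mouse template; divergent clusters use the
    next template in the configured cycle for the human side.
    """
    shapes = cfg.cluster_shapes
    base = shapes[cluster % len(shapes)]
    if species == "mouse" or conserved[cluster]:
        return base
    return shapes[(cluster + 1) % len(shapes)]


# ---------------------------------------------------------------------------
# expression experiment
# ---------------------------------------------------------------------------

def generate_experiment(config: SimConfig):
    """Simulate the full two-species expression experiment.

    Returns ``(human, mouse, probe_map_human, probe_map_mouse, pairs,
    calls_human, calls_mouse, truth)`` where the first two elements are
    :class:`TimeCourseMatrix` objects, the probe maps are probe->gene
    Series, ``pairs`` is the ortholog table, the call matrices hold P/M/A
    letters per probe and array, and ``truth`` is the
    :class:`~orthotime.containers.GroundTruth` record.

    Identical configs (including seed) give identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    k = config.n_clusters
    s_max = config.mouse_days[-1]

    width = len(str(n))
    human_genes = [f"HSG{i:0{width}d}" for i in range(1, n + 1)]
    mouse_genes = [f"MUG{i:0{width}d}" for i in range(1, n + 1)]

    # balanced random cluster assignment
    clusters = rng.permutation(np.arange(n) % k)
    n_conserved = int(round(config.conserved_fraction * k))
    conserved = np.zeros(k, dtype=bool)
    conserved[:n_conserved] = True

    assignments = pd.DataFrame(
        {"human_gene": human_genes, "mouse_gene": mouse_genes, "cluster": clusters}
    )
    shapes = {}
    for sp in ("human", "mouse"):
        for c in range(k):
            shapes[(sp, c)] = _species_shape(config, sp, c, conserved)

    silent = {
        sp: rng.random(n) < config.presence_absent_fraction
        for sp in ("human", "mouse")
    }

    # per-gene heterogeneity: a smooth random deviation from the cluster
    # template, defined in mouse time via 5 equidistant knots; conserved
    # genes keep the same deviation in both species
    jitter_nodes = np.linspace(0.0, s_max, 5)
    jitter_mouse = rng.normal(0.0, config.gene_shape_jitter, (n, 5))
    jitter_human = jitter_mouse.copy()
    divergent_gene = ~conserved[clusters]
    jitter_human[divergent_gene] = rng.normal(
        0.0, config.gene_shape_jitter, (int(divergent_gene.sum()), 5)
    )
    jitter = {"human": jitter_human, "mouse": jitter_mouse}

    outputs = {}
    for sp, genes, days in (
        ("human", human_genes, config.human_days),
        ("mouse", mouse_genes, config.mouse_days),
    ):
        days = np.asarray(days, dtype=float)
        s = days / config.time_dilation if sp == "human" else days
        # per-cluster mean profiles on this species' grid
        half_amp = config.amplitude / 2.0
        cluster_profiles = np.stack(
            [half_amp * shape_value(shapes[(sp, c)], s, s_max) for c in range(k)]
        )
        gene_signal = config.baseline + cluster_profiles[clusters]
        s_clip = np.clip(s, 0.0, s_max)
        gene_jitter = np.stack(
            [np.interp(s_clip, jitter_nodes, row) for row in jitter[sp]]
        )
        gene_signal = gene_signal + gene_jitter
        gene_signal[silent[sp]] = config.silent_baseline

        n_probes = 1 + rng.poisson(max(config.probes_per_gene_mean - 1.0, 0.0), n)
        n_probes = np.minimum(n_probes, config.probes_per_gene_max)

        rows, probe_ids, probe_gene = [], [], []
        n_samples = len(days) * config.n_replicates
        for gi, g in enumerate(genes):
            for p in range(1, n_probes[gi] + 1):
                offset = rng.normal(0.0, config.probe_offset_sd)
                # probe-specific attenuation keeps one probe closest to the
                # gene signal; creates the representative-probe problem
                gain = 1.0 if p == 1 else rng.uniform(0.3, 1.0)
                mean = config.baseline + gain * (
                    gene_signal[gi] - config.baseline
                ) + offset
                noise = rng.normal(0.0, config.noise_sd,
                                   (len(days), config.n_replicates))
                rows.append((mean[:, None] + noise).reshape(n_samples))
                probe_ids.append(f"{g}_p{p}")
                probe_gene.append(g)

        columns = pd.MultiIndex.from_product(
            [days, range(1, config.n_replicates + 1)], names=["day", "replicate"]
        )
        values = pd.DataFrame(np.array(rows), index=pd.Index(probe_ids,
                              name="probe_id"), columns=columns)
        matrix = TimeCourseMatrix(sp, tuple(days), config.n_replicates, values)
        probe_map = pd.Series(probe_gene, index=values.index, name="gene_id")

        # detection calls: silent genes are called A, expressed mostly P
        silent_probe = np.asarray(silent[sp])[
            pd.Index(genes).get_indexer(probe_gene)
        ]
        u = rng.random((len(probe_ids), n_samples))
        calls = np.where(u < 0.97, "P", "M")
        calls[silent_probe] = np.where(u[silent_probe] < 0.97, "A", "M")
        calls = pd.DataFrame(calls, index=values.index, columns=columns)

        outputs[sp] = (matrix, probe_map, calls)

    truth = GroundTruth(
        assignments=assignments,
        cluster_shapes=shapes,
        silent={
            "human": {g for g, s_ in zip(human_genes, silent["human"]) if s_},
            "mouse": {g for g, s_ in zip(mouse_genes, silent["mouse"]) if s_},
        },
        time_dilation=config.time_dilation,
    )
    pairs = assignments[["human_gene", "mouse_gene"]].copy()
    return (
        outputs["human"][0], outputs["mouse"][0],
        outputs["human"][1], outputs["mouse"][1],
        pairs,
        outputs["human"][2], outputs["mouse"][2],
        truth,
    )


# ---------------------------------------------------------------------------
# motif library
# ---------------------------------------------------------------------------

def generate_motif_library(
    n_motifs: int,
    width_range: tuple[int, int] = (8, 10),
    seed: int = 0,
    dominant_range: tuple[float, float] = (0.75, 0.95),
    min_ic_per_column: float = 0.5,
) -> MotifLibrary:
    """Random PWMs with one dominant base per column.

    Each column puts a probability drawn from ``dominant_range`` on a random
    consensus base and splits the rest evenly.  Motifs are redrawn until
    their mean per-column information content reaches
    ``min_ic_per_column`` bits and all consensus strings are distinct.
    """
    lo, hi = width_range
    if lo < 4 or hi < lo:
        raise ValueError("width_range must satisfy 4 <= min <= max")
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    rng = np.random.default_rng(seed)
    motifs: list[PWM] = []
    seen = set()
    while len(motifs) < n_motifs:
        w = int(rng.integers(lo, hi + 1))
        consensus = rng.integers(0, 4, w)
        dom = rng.uniform(*dominant_range, w)
        probs = np.full((4, w), 0.0)
        for j in range(w):
            probs[:, j] = (1.0 - dom[j]) / 3.0
            probs[consensus[j], j] = dom[j]
        pwm = PWM(f"motif_{len(motifs) + 1:03d}", probs)
        if pwm.information_content() / w < min_ic_per_column:
            continue
        if pwm.consensus in seen:
            continue
        seen.add(pwm.consensus)
        motifs.append(pwm)
    return MotifLibrary(motifs)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _sample_site(pwm: PWM, rng: np.random.Generator,
                 min_quality: float) -> str:
    """Draw a site from the PWM, rejecting low-scoring draws.

    Sites are resampled until their log-odds score reaches ``min_quality``
    of the maximum achievable score, so that planted occurrences are
    detectable at the matching scan threshold; after 100 failures the
    consensus is used.
    """
    lo = pwm.log_odds()
    target = min_quality * pwm.max_score()
    for _ in range(100):
        idx = np.array(
            [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.width)]
        )
        if lo[idx, np.arange(pwm.width)].sum() >= target:
            return "".join(BASES[i] for i in idx)
    return pwm.consensus


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def generate_promoters(
    genes: list[str],
    motif_library: MotifLibrary,
    planted_map: dict[str, str],
    promoter_length: int = 1000,
    background_gc: float = 0.5,
    sites_per_promoter: int = 1,
    seed: int = 0,
    min_site_quality: float = 0.85,
):
    """Simulate promoter sequences with planted motif occurrences.

    ``planted_map`` maps gene id -> motif id; genes not in the map receive
    pure background sequence (iid nucleotides at ``background_gc``).
    Returns ``(promoters, sites)`` where ``promoters`` maps gene -> sequence
    and ``sites`` is a DataFrame of implanted occurrences
    (gene, motif, offset, strand).
    """
    if motif_library and promoter_length < motif_library.max_width:
        raise ValueError("promoter_length shorter than the widest motif")
    unknown = {m for m in planted_map.values()} - set(motif_library.motif_ids)
    if unknown:
        raise ValueError(f"planted motifs not in library: {sorted(unknown)}")
    missing = set(planted_map) - set(genes)
    if missing:
        raise ValueError(f"planted genes not in gene list: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    p = np.array([(1 - background_gc) / 2, background_gc / 2,
                  background_gc / 2, (1 - background_gc) / 2])
    promoters: dict[str, str] = {}
    site_rows = []
    for gene in genes:
        seq = rng.choice(list(BASES), size=promoter_length, p=p)
        seq = "".join(seq)
        motif_id = planted_map.get(gene)
        if motif_id is not None:
            pwm = motif_library[motif_id]
            for _ in range(sites_per_promoter):
                site = _sample_site(pwm, rng, min_site_quality)
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = site if strand == "+" else _revcomp(site)
                offset = int(rng.integers(0, promoter_length - pwm.width + 1))
                seq = seq[:offset] + inserted + seq[offset + pwm.width:]
                site_rows.append((gene, motif_id, offset, strand))
        promoters[gene] = seq
    sites = pd.DataFrame(site_rows, columns=["gene", "motif", "offset", "strand"])
    return promoters, sites


def plant_motif_maps(
    truth: GroundTruth,
    library: MotifLibrary,
) -> dict[str, dict[str, str]]:
    """Assign one planted motif per non-flat cluster and species.

    Conserved clusters (same shape template in both species) receive the
    same motif in human and mouse; shape-divergent clusters receive a
    different motif on the human side, emulating divergent regulation.
    Flat clusters model non-regulated genes and get no motif.  Updates
    ``truth.planted_motifs`` and returns per-species gene -> motif maps.
    """
    clusters = sorted(truth.assignments["cluster"].unique())
    regulated = [
        c for c in clusters if truth.cluster_shapes[("mouse", c)] != "flat"
    ]
    if 2 * len(regulated) > len(library):
        # enough motifs for a distinct human motif on divergent clusters?
        divergent = [
            c for c in regulated
            if truth.cluster_shapes[("human", c)]
            != truth.cluster_shapes[("mouse", c)]
        ]
        if len(regulated) + len(divergent) > len(library):
            raise ValueError("motif library too small for planted clusters")
    maps: dict[str, dict[str, str]] = {"human": {}, "mouse": {}}
    next_free = len(regulated)
    for idx, c in enumerate(regulated):
        mouse_motif = library.motifs[idx].motif_id
        truth.planted_motifs[("mouse", c)] = mouse_motif
        if truth.cluster_shapes[("human", c)] == truth.cluster_shapes[
            ("mouse", c)
        ]:
            human_motif = mouse_motif
        else:
            human_motif = library.motifs[next_free].motif_id
            next_free += 1
        truth.planted_motifs[("human", c)] = human_motif
        members = truth.assignments[truth.assignments["cluster"] == c]
        for g in members["mouse_gene"]:
            maps["mouse"][g] = mouse_motif
        for g in members["human_gene"]:
            maps["human"][g] = human_motif
    return maps


def generate_annotation(
    truth: GroundTruth,
    species: str = "human",
    n_random_terms: int = 3,
    term_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Toy gene->term annotation table for enrichment testing.

    One term per planted cluster (its member genes) plus ``n_random_terms``
    random gene sets, emulating a flat functional-category table.
    """
    rng = np.random.default_rng(seed)
    col = f"{species}_gene"
    rows = []
    for c, sub in truth.assignments.groupby("cluster"):
        for g in sub[col]:
            rows.append((g, f"cluster_term_{c}"))
    all_genes = truth.assignments[col].to_numpy()
    for t in range(n_random_terms):
        size = min(term_size, len(all_genes))
        for g in rng.choice(all_genes, size=size, replace=False):
            rows.append((g, f"random_term_{t}"))
    return pd.DataFrame(rows, columns=["gene_id", "term"])
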