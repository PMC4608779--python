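"""Promoter motif scanning and binding-site overrepresentation statistics.

Promoters of a gene group (typically a co-expression cluster) are scanned
on both strands with position weight matrices; a position is a hit when
its log2-odds score (motif vs background base composition, pseudocount
smoothed) reaches a configurable fraction of the motif's maximum
achievable score.  Overrepresentation of a motif in the group is tested
against a background promoter set -- the least-varying expressed genes --
with an upper-tail hypergeometric test on site *density*: scannable
positions (sequence length - width + 1, times two strands) form the
population, hits are the successes, and the group's positions are the
draws.

A motif is assigned to a group when its density p-value passes a
Bonferroni cutoff (0.05 / library size) and at least 40% of the group's
promoters carry a site.  An empirical null from size-matched random gene
groups calibrates a stricter cutoff, and hypergeometric list-overlap
p-values quantify whether two groups' motif lists are more similar than
chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .containers import BASE_INDEX, MotifLibrary, PWM

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)  # 4 == N / unknown
    for base, i in BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8)
              == ord(base)] = i
    return codes


def _window_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Score every window of len(logodds columns) against the matrix.

    ``logodds`` is (4, w); a fifth row of -inf is appended for N bases.
    Returns an array of length len(codes) - w + 1.
    """
    w = logodds.shape[1]
    if len(codes) < w:
        return np.empty(0)
    ext = np.vstack([logodds, np.full((1, w), -np.inf)])
    windows = sliding_window_view(codes, w)
    return ext[windows, np.arange(w)].sum(axis=1)


def scan_promoter(
    sequence: str,
    pwm: PWM,
    min_score_fraction: float = 0.85,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Find PWM hits on both strands of a promoter sequence.

    A hit is a window whose log2-odds score is at least
    ``min_score_fraction`` of the motif's maximum achievable score.
    Offsets are 0-based on the forward strand; ``N`` bases never match.
    Returns a DataFrame (offset, strand, score) sorted by offset.
    """
    if not 0 < min_score_fraction <= 1:
        raise ValueError("min_score_fraction must lie in (0, 1]")
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
    codes = _encode(sequence)
    threshold = min_score_fraction * pwm.max_score(background)
    rows = []
    for strand, matrix in (
        ("+", pwm.log_odds(background)),
        ("-", pwm.reverse_complement().log_odds(background)),
    ):
        scores = _window_scores(codes, matrix)
        for off in np.nonzero(scores >= threshold)[0]:
            rows.append((int(off), strand, float(scores[off])))
    return (
        pd.DataFrame(rows, columns=["offset", "strand", "score"])
        .sort_values(["offset", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )


def base_frequencies(promoters: dict[str, str]) -> np.ndarray:
    """A/C/G/T frequencies pooled over a promoter set (N ignored)."""
    counts = np.zeros(4)
    for seq in promoters.values():
        codes = _encode(seq.upper())
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def hit_count_table(
    promoters: dict[str, str],
    library: MotifLibrary,
    min_score_fraction: float = 0.85,
    background: np.ndarray | None = None,
):
    """Hit counts per (promoter, motif) plus scannable position counts.

    Returns ``(counts, positions)``: ``counts`` is a genes x motifs
    DataFrame of hit numbers; ``positions`` is a genes x motifs DataFrame
    of scannable positions ((L - w + 1) * 2 strands).  Scanning once and
    reusing the table makes group-level statistics cheap.
    """
    genes = list(promoters)
    # concatenate all promoters with N spacers; windows that straddle a
    # boundary contain an N and score -inf, so they can never be hits
    spacer = np.full(library.max_width, 4, dtype=np.int8)
    chunks, starts, lengths, pos = [], [], [], 0
    for g in genes:
        codes = _encode(promoters[g].upper())
        starts.append(pos)
        lengths.append(len(codes))
        chunks.append(codes)
        chunks.append(spacer)
        pos += len(codes) + len(spacer)
    big = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int8)
    starts = np.asarray(starts)
    lengths = np.asarray(lengths)

    counts = np.zeros((len(genes), len(library)), dtype=int)
    positions = np.zeros((len(genes), len(library)), dtype=int)
    for j, pwm in enumerate(library):
        positions[:, j] = 2 * np.maximum(lengths - pwm.width + 1, 0)
        threshold = min_score_fraction * pwm.max_score(background)
        for matrix in (
            pwm.log_odds(background),
            pwm.reverse_complement().log_odds(background),
        ):
            scores = _window_scores(big, matrix)
            hit_at = np.nonzero(scores >= threshold)[0]
            if len(hit_at):
                owner = np.searchsorted(starts, hit_at, side="right") - 1
                counts[:, j] += np.bincount(owner, minlength=len(genes))
    idx = pd.Index(genes, name="gene")
    cols = pd.Index(library.motif_ids, name="motif")
    return (
        pd.DataFrame(counts, index=idx, columns=cols),
        pd.DataFrame(positions, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# background construction
# ---------------------------------------------------------------------------

def build_background(
    gene_matrix,
    status: pd.DataFrame,
    n: int = 500,
    gc_correct: bool = False,
    promoters: dict[str, str] | None = None,
    foreground_genes: list[str] | None = None,
    seed: int = 0,
) -> list[str]:
    """Background gene set: the ``n`` least-varying expressed genes.

    Genes must be expressed according to their presence calls; among
    those, the ``n`` with the smallest replicate-mean profile variance are
    taken (ties broken by gene id).  With ``gc_correct`` the background is
    resampled (with replacement where a stratum is short) so that its
    promoter GC-content histogram over 5% bins matches the foreground's.
    """
    expressed = status.index[status["expressed"]]
    expressed = expressed.intersection(gene_matrix.probe_ids)
    if len(expressed) < n:
        raise ValueError(
            f"only {len(expressed)} expressed genes, need {n} for background"
        )
    variance = (
        gene_matrix.replicate_mean().loc[expressed].var(axis=1, ddof=1)
    )
    order = variance.sort_values(kind="mergesort").index
    chosen = list(order[:n])
    if not gc_correct:
        return chosen
    if promoters is None or foreground_genes is None:
        raise ValueError("gc_correct needs promoters and foreground_genes")

    def gc_bin(seq: str) -> int:
        gc = (seq.count("G") + seq.count("C")) / max(len(seq), 1)
        return min(int(gc / 0.05), 19)

    rng = np.random.default_rng(seed)
    fg_bins = pd.Series([gc_bin(promoters[g]) for g in foreground_genes])
    bg_bins = pd.Series({g: gc_bin(promoters[g]) for g in chosen})
    target = (fg_bins.value_counts(normalize=True) * n).round().astype(int)
    out: list[str] = []
    for b, want in target.items():
        pool = list(bg_bins.index[bg_bins == b])
        if not pool:
            continue
        out.extend(
            rng.choice(pool, size=want, replace=len(pool) < want).tolist()
        )
    return out if out else chosen


# ---------------------------------------------------------------------------
# hypergeometric statistics
# ---------------------------------------------------------------------------

@dataclass
class DensityEnrichment:
    motif_id: str
    k_fg: int
    n_fg: int
    k_bg: int
    n_bg: int
    p_value: float
    coverage: float = float("nan")


def density_enrichment(k_fg: int, n_fg: int, k_bg: int, n_bg: int) -> float:
    """Upper-tail hypergeometric p-value for site density.

    Population: all scannable positions (foreground + background);
    successes: all hits; draws: foreground positions; observed: foreground
    hits.  ``p = P(X >= k_fg)``.
    """
    if n_fg <= 0 or n_bg <= 0:
        raise ValueError("zero scannable positions")
    if k_fg > n_fg or k_bg > n_bg:
        raise ValueError("hit count exceeds scannable positions")
    p = float(stats.hypergeom.sf(k_fg - 1, n_fg + n_bg, k_fg + k_bg, n_fg))
    return min(p, 1.0)


def list_overlap(list_a, list_b, total_motifs: int) -> dict:
    """Hypergeometric p-value for the overlap of two motif lists.

    ``p = P(X >= o)`` with X ~ Hypergeometric(M=total_motifs, K=|A|,
    n=|B|).  Small p means the two lists share more motifs than expected
    for random lists of their sizes.
    """
    a, b = set(list_a), set(list_b)
    if total_motifs < max(len(a), len(b)):
        raise ValueError("total_motifs smaller than a list")
    o = len(a & b)
    p = float(stats.hypergeom.sf(o - 1, total_motifs, len(a), len(b)))
    return {
        "a": len(a),
        "b": len(b),
        "overlap": o,
        "total_motifs": total_motifs,
        "p_value": min(p, 1.0),
    }


# ---------------------------------------------------------------------------
# group-level assignment
# ---------------------------------------------------------------------------

def _group_stats(
    group_genes, counts: pd.DataFrame, positions: pd.DataFrame
):
    sub_c = counts.loc[group_genes]
    sub_p = positions.loc[group_genes]
    return sub_c.sum(axis=0), sub_p.sum(axis=0), (sub_c > 0).mean(axis=0)


def assign_tfbs(
    group_genes: list[str],
    promoters: dict[str, str],
    library: MotifLibrary,
    background_genes: list[str],
    alpha: float | None = None,
    min_coverage: float = 0.40,
    min_score_fraction: float = 0.85,
    precomputed: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Density enrichment of every motif in a gene group vs background.

    Returns one row per motif with hit counts, position counts, coverage
    (fraction of group promoters with >= 1 hit), the hypergeometric
    p-value, and ``kept`` -- whether the motif passes both the Bonferroni
    cutoff (``alpha`` defaults to 0.05 / library size) and the 40%
    coverage condition.  Sorted by p-value.
    """
    if alpha is None:
        alpha = 0.05 / len(library)
    missing = [g for g in group_genes if g not in promoters]
    if missing:
        log.warning("skipping %d group genes without promoters", len(missing))
        group_genes = [g for g in group_genes if g in promoters]
    bg_genes = [g for g in background_genes if g in promoters]

    if precomputed is None:
        bg_freqs = base_frequencies({g: promoters[g] for g in bg_genes})
        counts, positions = hit_count_table(
            {g: promoters[g] for g in set(group_genes) | set(bg_genes)},
            library, min_score_fraction, bg_freqs,
        )
    else:
        counts, positions = precomputed

    k_fg, n_fg, coverage = _group_stats(group_genes, counts, positions)
    k_bg, n_bg, _ = _group_stats(bg_genes, counts, positions)

    rows = []
    for motif in library.motif_ids:
        p = density_enrichment(
            int(k_fg[motif]), int(n_fg[motif]), int(k_bg[motif]), int(n_bg[motif])
        )
        rows.append(
            {
                "motif": motif,
                "k_fg": int(k_fg[motif]),
                "n_fg": int(n_fg[motif]),
                "k_bg": int(k_bg[motif]),
                "n_bg": int(n_bg[motif]),
                "coverage": float(coverage[motif]),
                "p_value": p,
                "kept": p <= alpha and coverage[motif] >= min_coverage,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["p_value", "motif"], kind="mergesort")
        .reset_index(drop=True)
    )


def random_group_null(
    sizes: list[int],
    n_random: int,
    expressed_genes: list[str],
    promoters: dict[str, str],
    library: MotifLibrary,
    background_genes: list[str],
    seed: int = 0,
    min_score_fraction: float = 0.85,
    min_n_random: int = 100,
):
    """Empirical null of density p-values for random gene groups.

    Draws ``n_random`` groups (sizes cycled from ``sizes``) without
    replacement from the expressed genes and records every per-motif
    density p-value plus the per-group minimum.  The returned empirical
    cutoff is the smallest p-value seen in the null: real groups below it
    are enriched beyond anything random groups achieved.

    Returns ``(pvalues, min_per_group, cutoff)`` where ``pvalues`` is a
    long DataFrame (group, size, motif, p_value).
    """
    if n_random < min_n_random:
        raise ValueError(f"n_random must be >= {min_n_random}")
    pool = [g for g in expressed_genes if g in promoters]
    if max(sizes) > len(pool):
        raise ValueError("group size exceeds number of expressed genes")
    rng = np.random.default_rng(seed)
    bg_genes = [g for g in background_genes if g in promoters]
    bg_freqs = base_frequencies({g: promoters[g] for g in bg_genes})
    counts, positions = hit_count_table(
        {g: promoters[g] for g in set(pool) | set(bg_genes)},
        library, min_score_fraction, bg_freqs,
    )
    k_bg, n_bg, _ = _group_stats(bg_genes, counts, positions)

    rows = []
    for rep in range(n_random):
        size = sizes[rep % len(sizes)]
        group = rng.choice(pool, size=size, replace=False)
        k_fg, n_fg, _ = _group_stats(list(group), counts, positions)
        for motif in library.motif_ids:
            p = density_enrichment(
                int(k_fg[motif]), int(n_fg[motif]),
                int(k_bg[motif]), int(n_bg[motif]),
            )
            rows.append((rep, size, motif, p))
    pvalues = pd.DataFrame(rows, columns=["group", "size", "motif", "p_value"])
    min_per_group = pvalues.groupby("group")["p_value"].min()
    cutoff = float(pvalues["p_value"].min())
    return pvalues, min_per_group, cutoff


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def promoter_expression_report(
    cluster_pccs: pd.DataFrame,
    enrichments: dict[str, dict[int, pd.DataFrame]],
    total_motifs: int,
    strict_cutoff: float = 1e-9,
    min_coverage: float = 0.40,
):
    """Combine expression and promoter similarity per cluster.

    ``cluster_pccs``: table with columns ``cluster`` and ``pcc`` (mean
    expression-profile correlation).  ``enrichments`` maps species ->
    cluster -> :func:`assign_tfbs` table.

    Returns ``(scatter, counts, counts_pcc)``:

    * ``scatter`` -- per cluster: expression PCC, the human/mouse kept-list
      sizes, their overlap and its hypergeometric p-value (expression vs
      promoter similarity plane);
    * ``counts`` -- per motif: number of clusters per species with density
      p below ``strict_cutoff`` (and coverage above the gate);
    * ``counts_pcc`` -- Pearson correlation of the two count vectors.
    """
    scatter_rows = []
    for _, row in cluster_pccs.iterrows():
        c = int(row["cluster"])
        lists = {}
        for sp in ("human", "mouse"):
            tab = enrichments[sp][c]
            lists[sp] = set(tab.loc[tab["kept"], "motif"])
        ov = list_overlap(lists["human"], lists["mouse"], total_motifs)
        scatter_rows.append(
            {
                "cluster": c,
                "pcc": float(row["pcc"]),
                "n_human": ov["a"],
                "n_mouse": ov["b"],
                "overlap": ov["overlap"],
                "overlap_p": ov["p_value"],
            }
        )
    scatter = pd.DataFrame(scatter_rows)

    count_rows = []
    motif_ids = None
    for sp in ("human", "mouse"):
        any_cluster = next(iter(enrichments[sp].values()))
        motif_ids = list(any_cluster["motif"])
        break
    for motif in motif_ids:
        row = {"motif": motif}
        for sp in ("human", "mouse"):
            n = 0
            for c, tab in enrichments[sp].items():
                rec = tab.set_index("motif").loc[motif]
                if (
                    rec["p_value"] < strict_cutoff
                    and rec["coverage"] >= min_coverage
                ):
                    n += 1
            row[f"n_clusters_{sp}"] = n
        count_rows.append(row)
    counts = pd.DataFrame(count_rows)
    h = counts["n_clusters_human"].to_numpy(dtype=float)
    m = counts["n_clusters_mouse"].to_numpy(dtype=float)
    if h.std() == 0 or m.std() == 0:
        counts_pcc = float("nan")
    else:
        counts_pcc = float(np.corrcoef(h, m)[0, 1])
    return scatter, counts, counts_pcc
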