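"""Probe-to-gene reduction, standardization, presence calls and enrichment.

These steps turn platform-level probe matrices into gene-level standardized
profiles and produce the bookkeeping tables of the study design: per-gene
expression status from detection calls, per-time-point upregulated gene
sets, hypergeometric term enrichment, and the selection of differentially
regulated ortholog pairs that feeds the comparison and clustering stages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TimeCourseMatrix

log = logging.getLogger(__name__)

_CALL_ORDER = {"A": 0, "M": 1, "P": 2}


# ---------------------------------------------------------------------------
# probe -> gene
# ---------------------------------------------------------------------------

def select_representative_probe(
    matrix: TimeCourseMatrix,
    probe_map: pd.Series,
    criterion: str = "variance",
):
    """Reduce a probe-level matrix to one representative probe per gene.

    The representative is the probe whose replicate-averaged profile has
    the largest change in expression: by default the largest sample
    variance across days (``criterion="range"`` uses max - min instead).
    Exact ties are broken by the lexicographically smallest probe id.

    Returns ``(gene_matrix, audit)``: the gene-level
    :class:`~orthotime.containers.TimeCourseMatrix` (rows indexed by gene
    id) and an audit table with the chosen probe and its score per gene.
    """
    probe_map = probe_map.reindex(matrix.probe_ids)
    unmapped = probe_map.index[probe_map.isna()]
    if len(unmapped):
        log.warning("%d probes without gene mapping ignored", len(unmapped))
        probe_map = probe_map.dropna()

    mean_prof = matrix.replicate_mean().loc[probe_map.index]
    if criterion == "variance":
        score = mean_prof.var(axis=1, ddof=1)
    elif criterion == "range":
        score = mean_prof.max(axis=1) - mean_prof.min(axis=1)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    # stable pick: highest score, then smallest probe id
    audit = (
        pd.DataFrame({"gene_id": probe_map, "score": score})
        .rename_axis("probe_id")
        .reset_index()
        .sort_values(["gene_id", "score", "probe_id"],
                     ascending=[True, False, True], kind="mergesort")
    )
    chosen = audit.groupby("gene_id", sort=True).first()
    n_const = int((chosen["score"] == 0).sum())
    if n_const:
        log.warning("%d genes have only constant probes", n_const)

    gene_values = matrix.values.loc[chosen["probe_id"]]
    gene_values.index = pd.Index(chosen.index, name="gene_id")
    gene_matrix = TimeCourseMatrix(
        matrix.species, matrix.days, matrix.n_replicates, gene_values
    )
    return gene_matrix, chosen.reset_index()


def standardize(gene_matrix: TimeCourseMatrix):
    """Replicate-average, mean-center and scale profiles to unit SD.

    Standardization makes downstream comparisons sensitive to profile
    *shape* only.  Profiles with zero variance carry no shape information
    and are excluded (returned separately).

    Returns ``(profiles, excluded)``: a genes x days DataFrame with
    row-wise sample SD 1, and the list of excluded gene ids.
    """
    if len(gene_matrix.days) < 3:
        raise ValueError("standardization needs at least 3 time points")
    mean_prof = gene_matrix.replicate_mean()
    sd = mean_prof.std(axis=1, ddof=1)
    excluded = list(mean_prof.index[sd == 0.0])
    if excluded:
        log.info("excluding %d zero-variance profiles", len(excluded))
    kept = mean_prof.loc[sd > 0.0]
    out = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[kept.index], axis=0)
    return out, excluded


# ---------------------------------------------------------------------------
# presence / absence
# ---------------------------------------------------------------------------

def aggregate_presence(
    calls: pd.DataFrame,
    probe_map: pd.Series,
    k: int = 3,
) -> pd.DataFrame:
    """Gene-level expression status from per-array P/M/A calls.

    Per array, the gene call is the maximum over its probes under the
    order P > M > A (one detected probe set suffices).  ``presence_count``
    is the number of arrays on which the gene call is P, and a gene is
    ``expressed`` when that count reaches the threshold ``k``.
    """
    if k < 1:
        raise ValueError("presence threshold k must be >= 1")
    probe_map = probe_map.reindex(calls.index)
    if probe_map.isna().any():
        log.warning("%d probes without gene mapping ignored",
                    int(probe_map.isna().sum()))
        probe_map = probe_map.dropna()
    coded = calls.loc[probe_map.index].apply(
        lambda col: col.map(_CALL_ORDER)
    ).astype(int)
    gene_max = coded.groupby(probe_map).max()
    presence_count = (gene_max == _CALL_ORDER["P"]).sum(axis=1)
    out = pd.DataFrame(
        {
            "presence_count": presence_count,
            "expressed": presence_count >= k,
        }
    )
    out.index.name = "gene_id"
    return out


def presence_cross_table(
    status_human: pd.DataFrame,
    status_mouse: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.Series:
    """Percentages of ortholog pairs by joint expression status.

    Categories ``hESC-/mESC-``, ``hESC-/mESC+``, ``hESC+/mESC-`` and
    ``hESC+/mESC+`` partition the pairs, so the four percentages sum
    to 100.
    """
    h = status_human["expressed"].reindex(pairs["human_gene"]).to_numpy()
    m = status_mouse["expressed"].reindex(pairs["mouse_gene"]).to_numpy()
    labels = {
        "hESC- mESC-": (~h & ~m),
        "hESC- mESC+": (~h & m),
        "hESC+ mESC-": (h & ~m),
        "hESC+ mESC+": (h & m),
    }
    return pd.Series(
        {name: 100.0 * mask.mean() for name, mask in labels.items()}
    )


# ---------------------------------------------------------------------------
# regulation accounting
# ---------------------------------------------------------------------------

def upregulated_genes(gene_matrix: TimeCourseMatrix, fc: float = 2.0):
    """Genes upregulated relative to day 0 at each time point.

    A gene is upregulated at day t when its replicate-mean log2 expression
    exceeds the day-0 mean by at least ``log2(fc)``.  Returns
    ``(per_day, union)``: a dict day -> gene set for every day after 0,
    and the union over days.
    """
    if fc <= 1.0:
        raise ValueError("fold-change threshold must exceed 1")
    mean_prof = gene_matrix.replicate_mean()
    day0 = mean_prof.iloc[:, 0]
    lfc = np.log2(fc)
    per_day = {}
    for day in gene_matrix.days[1:]:
        mask = (mean_prof[day] - day0) >= lfc
        per_day[day] = set(mean_prof.index[mask])
    union = set().union(*per_day.values()) if per_day else set()
    return per_day, union


def term_enrichment(hits: set, term_genes: set, universe: set) -> dict:
    """Upper-tail hypergeometric enrichment of ``hits`` in ``term_genes``.

    Models drawing ``len(hits)`` genes without replacement from the
    universe and asks for the probability of at least the observed overlap
    with the term's genes: ``p = P(X >= overlap)``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not term_genes <= universe:
        raise ValueError("hits and term genes must be subsets of the universe")
    overlap = len(hits & term_genes)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe),
                                 len(term_genes), len(hits)))
    return {
        "overlap": overlap,
        "n_hits": len(hits),
        "n_term": len(term_genes),
        "n_universe": len(universe),
        "p_value": min(p, 1.0),
    }


def enrichment_table(
    hits: set, annotation: pd.DataFrame, universe: set
) -> pd.DataFrame:
    """Run :func:`term_enrichment` for every term in a gene->term table."""
    rows = []
    for term, sub in annotation.groupby("term"):
        genes = set(sub["gene_id"]) & universe
        if not genes:
            continue
        res = term_enrichment(hits & universe, genes, universe)
        rows.append(
            {
                "term": term,
                "n_hits": res["overlap"],
                "n_term": res["n_term"],
                "p": res["p_value"],
                "minus_log10_p": -np.log10(max(res["p_value"], 1e-300)),
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def select_diff_regulated(
    human_matrix: TimeCourseMatrix,
    mouse_matrix: TimeCourseMatrix,
    pairs: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Ortholog pairs differentially regulated in *both* species.

    A gene qualifies in a species when the absolute deviation of some
    day's replicate-mean from the gene's grand mean exceeds ``threshold``
    log2 units.  Only pairs qualifying on both sides are retained.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    def qualifying(matrix: TimeCourseMatrix) -> pd.Series:
        prof = matrix.replicate_mean()
        dev = prof.sub(prof.mean(axis=1), axis=0).abs().max(axis=1)
        return dev > threshold

    ok_h = qualifying(human_matrix).reindex(pairs["human_gene"])
    ok_m = qualifying(mouse_matrix).reindex(pairs["mouse_gene"])
    mask = ok_h.fillna(False).to_numpy() & ok_m.fillna(False).to_numpy()
    out = pairs.loc[mask].reset_index(drop=True)
    if out.empty:
        raise RuntimeError(
            "no ortholog pair passes the differential-regulation threshold "
            f"({threshold} log2 units in both species)"
        )
    return out
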