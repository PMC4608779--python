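"""Core data containers shared across the pipeline.

The pipeline compares early differentiation time courses of human and mouse
embryonic stem cells measured on two different microarray platforms.  The
central containers are:

* :class:`TimeCourseMatrix` -- log2 expression, probes x (day, replicate).
* standardized profiles -- plain ``pandas.DataFrame`` (genes x days) of
  replicate-averaged, mean-centered, unit-SD profiles.
* :class:`PWM` / :class:`MotifLibrary` -- position weight matrices used for
  promoter scanning.

Lightweight tables (probe->gene maps, ortholog pairs, presence calls) are
plain pandas objects; the TSV dialects are defined in :mod:`orthotime.io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class TimeCourseMatrix:
    """Log2 expression values for one species.

    Parameters
    ----------
    species:
        Free-form label, e.g. ``"human"`` or ``"mouse"``.
    days:
        Strictly increasing day grid starting at day 0 (the undifferentiated
        reference state).
    n_replicates:
        Number of biological replicates per time point.
    values:
        DataFrame indexed by probe (or gene) identifier with a two-level
        column MultiIndex ``(day, replicate)``; replicates are numbered
        ``1..n_replicates``.  No missing cells are allowed.
    """

    species: str
    days: tuple[float, ...]
    n_replicates: int
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.days = tuple(float(d) for d in self.days)
        if len(self.days) < 2 or any(
            b <= a for a, b in zip(self.days, self.days[1:])
        ):
            raise ValueError("day grid must be strictly increasing")
        if self.days[0] != 0.0:
            raise ValueError("day grid must start at day 0 (reference state)")
        expected = pd.MultiIndex.from_product(
            [self.days, range(1, self.n_replicates + 1)],
            names=["day", "replicate"],
        )
        if not self.values.columns.equals(expected):
            self.values = self.values.reindex(columns=expected)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def replicate_mean(self) -> pd.DataFrame:
        """Average replicates; returns probes x days DataFrame."""
        out = self.values.T.groupby(level="day").mean().T
        return out[list(self.days)]

    def subset(self, probes) -> "TimeCourseMatrix":
        return TimeCourseMatrix(
            self.species, self.days, self.n_replicates, self.values.loc[probes]
        )


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position weight matrix over {A, C, G, T}.

    ``probs`` has shape (4, width); every column sums to one.  Scoring uses
    log-odds against a background base composition after adding
    ``pseudocount`` to each cell (see :func:`orthotime.promoter_tfbs.scan_promoter`).
    """

    motif_id: str
    probs: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM probabilities must have shape (4, width)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def information_content(self) -> float:
        """Total information content in bits (uniform background)."""
        p = np.clip(self.probs, 1e-12, None)
        return float((p * np.log2(p / 0.25)).sum())

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """(4, width) log2-odds matrix, pseudocount-smoothed.

        ``background`` is a length-4 base-frequency vector; default uniform.
        """
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        background = background / background.sum()
        p = self.probs + self.pseudocount
        p = p / p.sum(axis=0, keepdims=True)
        return np.log2(p / background[:, None])

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background).max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1], self.pseudocount)


@dataclass
class MotifLibrary:
    """Ordered collection of PWMs with dict-style access by motif id."""

    motifs: list[PWM] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, motif_id: str) -> PWM:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)

    @property
    def motif_ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs]

    @property
    def max_width(self) -> int:
        return max(m.width for m in self.motifs)


# ---------------------------------------------------------------------------
# simulation ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Record of everything the simulator planted.

    ``assignments`` has one row per ortholog pair with columns
    ``human_gene``, ``mouse_gene``, ``cluster``.  ``cluster_shapes`` maps
    ``(species, cluster)`` to the shape-template name used for that cluster
    in that species.  ``planted_motifs`` maps ``(species, cluster)`` to a
    motif id (clusters without a planted motif are absent).  ``silent``
    holds the per-species sets of silent (not expressed) genes, keyed by the
    species' own gene ids.  ``planted_sites`` records implanted motif
    occurrences (species, gene, motif, offset, strand).
    """

    assignments: pd.DataFrame
    cluster_shapes: dict[tuple[str, int], str]
    planted_motifs: dict[tuple[str, int], str] = field(default_factory=dict)
    silent: dict[str, set[str]] = field(default_factory=dict)
    time_dilation: float = 1.0
    planted_sites: pd.DataFrame | None = None

    def cluster_of(self, species: str) -> pd.Series:
        """Gene -> cluster labels keyed by one species' gene ids."""
        col = f"{species}_gene"
        return self.assignments.set_index(col)["cluster"]

    def to_dict(self) -> dict:
        return {
            "assignments": self.assignments.to_dict(orient="list"),
            "cluster_shapes": {
                f"{sp}:{c}": shape for (sp, c), shape in self.cluster_shapes.items()
            },
            "planted_motifs": {
                f"{sp}:{c}": m for (sp, c), m in self.planted_motifs.items()
            },
            "silent": {sp: sorted(genes) for sp, genes in self.silent.items()},
            "time_dilation": self.time_dilation,
            "planted_sites": (
                None
                if self.planted_sites is None
                else self.planted_sites.to_dict(orient="list")
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        def unkey(m):
            out = {}
            for k, v in m.items():
                sp, c = k.rsplit(":", 1)
                out[(sp, int(c))] = v
            return out

        return cls(
            assignments=pd.DataFrame(d["assignments"])[
                ["human_gene", "mouse_gene", "cluster"]
            ],
            cluster_shapes=unkey(d["cluster_shapes"]),
            planted_motifs=unkey(d["planted_motifs"]),
            silent={sp: set(v) for sp, v in d["silent"].items()},
            time_dilation=d["time_dilation"],
            planted_sites=(
                None
                if d.get("planted_sites") is None
                else pd.DataFrame(d["planted_sites"])
            ),
        )


__all__ = [
    "BASES",
    "BASE_INDEX",
    "TimeCourseMatrix",
    "PWM",
    "MotifLibrary",
    "GroundTruth",
]
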