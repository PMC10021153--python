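"""Model/Results interface for the multimorbidity network analysis.

:class:`DiseaseNetworkModel` bundles one cohort stratum with the
analysis settings (edge thresholds, orientation rule, distance
transform, weighting flags); :meth:`DiseaseNetworkModel.fit` runs the
full chain — weighted prevalence, dyad matrix, 120 age-adjusted
pairwise logistic regressions, edge selection, network construction,
centrality and network attributes — and returns a
:class:`DiseaseNetworkResults` carrying every intermediate and a
``summary()`` table.

>>> model = DiseaseNetworkModel(cohort, or_min=1.2, alpha=0.05)
>>> res = model.fit()
>>> res.attributes.n_edges, res.attributes.density
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import descriptives as desc_mod
from . import graph as graph_mod
from .codebook import Cohort, DEFAULT_CODEBOOK, filter_multimorbid

__all__ = ["DiseaseNetworkModel", "DiseaseNetworkResults"]


class DiseaseNetworkModel:
    """Age-adjusted pairwise-association network model for one stratum.

    Parameters
    ----------
    cohort : Cohort
        The analysis cohort (one gender stratum in the standard design).
    or_min, alpha : float
        Edge-inclusion thresholds: adjusted OR >= ``or_min`` (inclusive)
        and p-value < ``alpha`` (exclusive).  Defaults 1.2 and 0.05.
    orientation : {"both-geomean", "first"}
        Symmetrization rule for the per-pair regressions.
    distance_transform : {"reciprocal", "inverse_log"}
        How OR edge weights become path distances.
    use_weights : bool
        Apply sampling weights in prevalences and regressions.
    robust_se : bool
        Sandwich standard errors in the regressions.
    bh : bool
        Benjamini-Hochberg correction across the 120 tests before
        thresholding (deviation from the raw-p rule; off by default).
    multimorbid_only : bool
        Restrict to records with >= 2 diseases before analysis (the
        standard study population; already-selected cohorts pass
        through unchanged).
    """

    def __init__(self, cohort: Cohort, or_min: float = 1.2, alpha: float = 0.05,
                 orientation: str = "both-geomean",
                 distance_transform: str = "reciprocal",
                 use_weights: bool = True, robust_se: bool = False,
                 bh: bool = False, multimorbid_only: bool = False):
        if or_min <= 0 or alpha <= 0:
            raise ValueError("thresholds must be positive")
        if orientation not in ("both-geomean", "first"):
            raise ValueError(f"unknown orientation {orientation!r}")
        self.cohort = cohort
        self.or_min = float(or_min)
        self.alpha = float(alpha)
        self.orientation = orientation
        self.distance_transform = distance_transform
        self.use_weights = bool(use_weights)
        self.robust_se = bool(robust_se)
        self.bh = bool(bh)
        self.multimorbid_only = bool(multimorbid_only)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, codebook=DEFAULT_CODEBOOK, **kwargs
                       ) -> "DiseaseNetworkModel":
        """Build from a raw cohort DataFrame (validated on entry)."""
        return cls(Cohort(df, codebook, "all"), **kwargs)

    def fit(self) -> "DiseaseNetworkResults":
        cohort = self.cohort
        if self.multimorbid_only and cohort.selection == "all":
            cohort = filter_multimorbid(cohort)

        prevalence = desc_mod.prevalence_table(cohort)
        dyads = desc_mod.dyad_matrix(cohort, weighted=self.use_weights)
        associations = assoc_mod.all_pairs(
            cohort, use_weights=self.use_weights, robust_se=self.robust_se,
            orientation=self.orientation)
        edges = assoc_mod.filter_edges(associations, self.or_min, self.alpha,
                                       bh=self.bh)
        network = graph_mod.build_network(
            prevalence, edges, nodes=tuple(cohort.codes),
            distance_transform=self.distance_transform)
        return DiseaseNetworkResults(
            model=self, cohort=cohort, prevalence=prevalence, dyads=dyads,
            associations=associations, edges=edges, network=network)


@dataclass
class DiseaseNetworkResults:
    """Fitted multimorbidity network with all intermediates.

    Attributes
    ----------
    prevalence : DataFrame
        Per-disease unweighted counts and weighted prevalences.
    dyads : DataFrame
        16 x 16 weighted co-occurrence matrix (diagonal NaN).
    associations : list of PairwiseAssociation
        Symmetrized age-adjusted OR/SE/p per unordered pair (120 rows).
    edges : list of EdgeRecord
        Inclusion decision per pair.
    network : DiseaseNetwork
        The thresholded weighted undirected network.
    """

    model: DiseaseNetworkModel
    cohort: Cohort
    prevalence: pd.DataFrame
    dyads: pd.DataFrame
    associations: list
    edges: list
    network: graph_mod.DiseaseNetwork
    _centrality: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def included_edges(self) -> list:
        return [e for e in self.edges if e.included]

    @property
    def centrality(self) -> pd.DataFrame:
        """Per-node degree/closeness/betweenness (computed lazily)."""
        if self._centrality is None:
            self._centrality = graph_mod.centrality_table(self.network)
        return self._centrality

    @property
    def attributes(self) -> graph_mod.NetworkAttributes:
        return graph_mod.network_attributes(self.network)

    def associations_frame(self) -> pd.DataFrame:
        return assoc_mod.associations_frame(self.associations, self.edges)

    def ranked_dyads(self, top_k: int = 5) -> list:
        return desc_mod.rank_dyads(self.dyads, top_k)

    def summary(self) -> str:
        """Plain-text summary: network attributes, top dyads, centralities."""
        attrs = self.attributes
        buf = StringIO()
        w = buf.write
        w("Multimorbidity disease network\n")
        w("==============================\n")
        w(f"Records analysed:        {self.cohort.n}  (selection={self.cohort.selection})\n")
        w(f"Edge rule:               OR >= {self.model.or_min}, p < {self.model.alpha}"
          f"{' (BH-adjusted)' if self.model.bh else ''}\n")
        w(f"Orientation:             {self.model.orientation}\n")
        w(f"Nodes / edges:           {attrs.n_nodes} / {attrs.n_edges}\n")
        w(f"Diameter ({attrs.distance_transform}):    {attrs.diameter:.4f}\n")
        w(f"Density:                 {attrs.density:.4f}\n\n")
        w("Top 5 dyads (weighted co-occurrence):\n")
        for (a, b), p in self.ranked_dyads(5):
            w(f"  {a:>4s}-{b:<4s} {100 * p:6.2f}%\n")
        w("\nNode centralities:\n")
        cent = self.centrality
        w(cent.to_string(index=False,
                         float_format=lambda v: f"{v:.4f}"))
        w("\n")
        return buf.getvalue()
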