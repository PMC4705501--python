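"""Model/Results interface over the ADM clustering machinery.

`ADM` is constructed from a network (or straight from an edge-list file)
with the algorithm's tunables; `fit()` executes the multi-restart protocol
and returns an `ADMResults` carrying the winning partition, its density
modularity, the snapshot trajectory of every restart, and convenience
methods for benchmarking against reference complexes, enrichment
annotation, and plotting.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import adm_core, evaluation
from .adm_core import ADMConfig, ADMResult
from .graph_io import (AnnotationTable, ModuleSet, PPINetwork,
                       read_edge_list, write_module_set)

__all__ = ["ADM", "ADMResults"]


class ADM:
    """Adaptive density-modularity module detector for a PPI network.

    Parameters
    ----------
    network
        The interaction network to partition (must have >= 1 edge to fit).
    restarts
        Independent runs of the multi-restart protocol; the run with the
        greatest density modularity wins.  Default 20.
    min_module_size
        Minimum protein count of a reported module.  Default 3.
    cad_form
        ``"consistent"`` or ``"eq5_as_printed"``; see
        :mod:`adm.density_modularity`.
    max_sweeps
        Safety cap on sweeps per stabilization.

    Examples
    --------
    >>> from adm import ADM, synthetic
    >>> net, truth = synthetic.generate(synthetic.PlantedSpec((8, 8, 8, 8), seed=7))
    >>> res = ADM(net).fit(seed=1)
    >>> len(res.modules)
    4
    """

    def __init__(self, network: PPINetwork, *, restarts: int = 20,
                 min_module_size: int = 3, cad_form: str = "consistent",
                 max_sweeps: int = 1000):
        self.network = network
        self.restarts = restarts
        self.min_module_size = min_module_size
        self.cad_form = cad_form
        self.max_sweeps = max_sweeps

    @classmethod
    def from_edge_list(cls, path: str | Path, format: str = "tsv",
                       **kwargs) -> "ADM":
        """Build the model straight from a TSV/SIF edge-list file."""
        return cls(read_edge_list(path, format=format), **kwargs)

    def _config(self, seed: int) -> ADMConfig:
        return ADMConfig(seed=seed, restarts=self.restarts,
                         min_module_size=self.min_module_size,
                         cad_form=self.cad_form, max_sweeps=self.max_sweeps)

    def fit(self, seed: int = 0) -> "ADMResults":
        """Run the multi-restart protocol; deterministic for a given seed."""
        result = adm_core.multi_restart(self.network, self._config(seed))
        return ADMResults(self, result, seed)


class ADMResults:
    """Fitted ADM partition with its diagnostics."""

    def __init__(self, model: ADM, result: ADMResult, seed: int):
        self.model = model
        self._result = result
        self.seed = seed

    # -- estimates -------------------------------------------------------

    @property
    def modules(self) -> ModuleSet:
        """Size-filtered predicted functional modules, largest first."""
        return self._result.filtered_modules

    @property
    def density_modularity(self) -> float:
        """D of the winning snapshot."""
        return self._result.best_D

    @property
    def best_partition(self):
        return self._result.best_partition

    @property
    def restart_scores(self) -> list[float]:
        """Best D of each restart (the winner is their maximum)."""
        return self._result.restart_scores

    @property
    def trajectory(self) -> pd.DataFrame:
        """Snapshot log: (restart, stage, module_count, D)."""
        return self._result.trajectory_frame()

    # -- evaluation ------------------------------------------------------

    def score(self, reference: ModuleSet,
              match_threshold: float = 0.2) -> dict[str, float]:
        """Benchmark the prediction against reference modules.

        Returns the standard report columns: predicted module count,
        matched count (overlap score >= ``match_threshold``), Sn, PPV and
        geometric-mean Acc.
        """
        T = evaluation.matching_matrix(reference, self.modules)
        sn = evaluation.sensitivity(T)
        pv = evaluation.ppv(T)
        return {
            "clusters": len(self.modules),
            "matched": evaluation.matched_count(reference, self.modules,
                                                match_threshold),
            "Sn": sn,
            "PPV": pv,
            "Acc": evaluation.accuracy(sn, pv),
        }

    def annotate(self, annotations: AnnotationTable,
                 alpha: float = 0.01) -> pd.DataFrame:
        """Hypergeometric best-term annotation of every predicted module."""
        return evaluation.annotate_modules(self.modules, annotations, alpha)

    # -- output ----------------------------------------------------------

    def save_modules(self, path: str | Path) -> None:
        write_module_set(self.modules, path)

    def plot_trajectory(self, ax=None):
        """Density modularity along each restart's agglomeration path."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.trajectory
        for restart, grp in frame.groupby("restart"):
            ax.plot(grp["module_count"], grp["D"], alpha=0.5,
                    label=f"restart {restart}")
        ax.axhline(self.density_modularity, ls="--", color="k", lw=0.8)
        ax.set_xlabel("module count")
        ax.set_ylabel("density modularity D")
        ax.invert_xaxis()
        return ax

    def summary(self) -> str:
        """Human-readable fit report."""
        net = self.model.network
        sizes = self.modules.sizes()
        lines = [
            "Adaptive Density Modularity (ADM) results",
            "=" * 45,
            f"Nodes:                {net.n_nodes}",
            f"Edges (L):            {net.L}",
            f"Restarts:             {self.model.restarts} (seed {self.seed})",
            f"CAD form:             {self.model.cad_form}",
            f"Best density mod. D:  {self.density_modularity:.6f}",
            f"Modules (>= {self.model.min_module_size} "
            f"proteins): {len(sizes)}",
            f"Module sizes:         "
            f"{', '.join(map(str, sizes)) if sizes else '-'}",
            "=" * 45,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<ADMResults: {len(self.modules)} modules, "
                f"D={self.density_modularity:.4f}>")
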