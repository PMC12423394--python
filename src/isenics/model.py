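"""The ISENICS model object: senescence scoring and classification of a
cohort of deconvolved immune-cell expression profiles.

Usage follows the model/results idiom::

    model = ISENICS(profiles, signature, sasp=sasp_genes)
    results = model.fit()
    print(results.summary())

``ISENICS`` holds the data and the engine configuration; ``fit`` computes
per-cell-type ICSS, senescence groups, per-sample STIME classes, SASP
concordance diagnostics, and the cell-type co-senescence network, returned
as an :class:`ISENICSResults` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import CoSenNetwork, SaspConcordance, cosenescence_network, sasp_concordance
from .classify import GroupAssignment, StimeLabel, classify_cohort, quartile_groups, top_bottom_groups
from .errors import ValidationError
from .io import ExpressionMatrix, GeneList, SignedGeneSet
from .scoring import AucellParams, GsvaParams, ScoreVector, icss


class ISENICS:
    """Identify senescent immune cells and samples in a cohort.

    Parameters
    ----------
    profiles : dict of cell type -> ExpressionMatrix
        Deconvolved cell-type-specific expression (genes x samples), or a
        single-entry dict for one matrix of cells.
    signature : SignedGeneSet
        Senescence signature; signed (CellAge/siAge style) or unsigned
        (SenMayo/SenCID style).
    sasp : GeneList, optional
        SASP genes for the concordance diagnostic.
    method : {"gsva", "aucell"}
        Scoring engine; GSVA suits cross-sample deconvolved profiles,
        AUCell suits single cells.
    """

    def __init__(
        self,
        profiles: dict[str, ExpressionMatrix] | ExpressionMatrix,
        signature: SignedGeneSet,
        sasp: GeneList | None = None,
        method: str = "gsva",
        params: GsvaParams | AucellParams | None = None,
    ):
        if isinstance(profiles, ExpressionMatrix):
            profiles = {"all": profiles}
        if not profiles:
            raise ValidationError("ISENICS needs at least one expression matrix")
        self.profiles = dict(profiles)
        self.signature = signature
        self.sasp = sasp
        self.method = method
        if params is None:
            params = GsvaParams() if method == "gsva" else AucellParams()
        self.params = params

    @classmethod
    def from_files(
        cls,
        matrix_paths: dict[str, str],
        gmt_path: str,
        signature_name: str,
        sasp_path: str | None = None,
        method: str = "gsva",
    ) -> "ISENICS":
        from .io import read_gene_list, read_matrix, read_signed_gmt

        profiles = {ct: read_matrix(p) for ct, p in matrix_paths.items()}
        signature = read_signed_gmt(gmt_path, signature_name)
        sasp = read_gene_list(sasp_path, "SASP") if sasp_path else None
        return cls(profiles, signature, sasp, method=method)

    def fit(
        self,
        scheme: str = "quartile",
        fraction: float = 0.25,
        network_p_threshold: float = 0.05,
        network_bh: bool = False,
    ) -> "ISENICSResults":
        """Score, group and classify the cohort.

        ``scheme`` is ``quartile`` (bulk convention) or
        ``top_bottom_fraction`` (single-cell convention with ``fraction``
        at each extreme).  The STIME vote always uses quartile groups, per
        cell type.
        """
        scores = {ct: icss(m, self.signature, self.method, self.params)
                  for ct, m in self.profiles.items()}
        if scheme == "quartile":
            groups = {ct: quartile_groups(sv) for ct, sv in scores.items()}
        elif scheme == "top_bottom_fraction":
            groups = {ct: top_bottom_groups(sv, fraction) for ct, sv in scores.items()}
        else:
            raise ValidationError(f"unknown scheme {scheme!r}")
        stime = classify_cohort(scores)
        sasp_res = None
        if self.sasp is not None:
            sasp_res = {
                ct: sasp_concordance(scores[ct], self.profiles[ct], self.sasp)
                for ct in scores
            }
        network = None
        if len(scores) >= 2:
            network = cosenescence_network(scores, p_threshold=network_p_threshold,
                                           bh=network_bh)
        return ISENICSResults(self, scores, groups, stime, sasp_res, network)


@dataclass
class ISENICSResults:
    """Fitted ISENICS scores, groups, sample classes and diagnostics."""

    model: ISENICS = field(repr=False)
    icss: dict[str, ScoreVector]
    groups: dict[str, GroupAssignment]
    stime: list[StimeLabel]
    sasp: dict[str, SaspConcordance] | None = None
    network: CoSenNetwork | None = None

    def icss_frame(self) -> pd.DataFrame:
        """Samples x cell types ICSS table (NaN where a sample is absent)."""
        return pd.DataFrame({ct: sv.to_series() for ct, sv in self.icss.items()})

    def stime_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stime:
            votes = list(s.votes.values())
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "label": s.label,
                    "n_high": votes.count("high"),
                    "n_low": votes.count("low"),
                    "n_celltypes": s.n_celltypes,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the fit."""
        lines = ["ISENICS results", "=" * 60]
        lines.append(f"signature: {self.model.signature.name} "
                     f"({'signed' if self.model.signature.signed else 'unsigned'}), "
                     f"engine: {self.model.method}")
        lines.append("")
        lines.append(f"{'cell type':<16}{'n':>6}{'mean ICSS':>12}{'low':>6}{'med':>6}{'high':>6}")
        for ct, sv in self.icss.items():
            labels = self.groups[ct].labels
            lines.append(
                f"{ct:<16}{len(sv.values):>6}{sv.values.mean():>12.4f}"
                f"{labels.count('low'):>6}{labels.count('medium'):>6}{labels.count('high'):>6}"
            )
        counts = {lab: 0 for lab in ("HSTIME", "MSTIME", "LSTIME")}
        for s in self.stime:
            counts[s.label] += 1
        lines.append("")
        lines.append("sample classes: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
        if self.sasp:
            lines.append("")
            for ct, sc in self.sasp.items():
                lines.append(
                    f"SASP concordance [{ct}]: positive fraction "
                    f"{sc.positive_fraction:.3f} over {sc.n_expressed} expressed genes"
                )
        if self.network is not None:
            lines.append("")
            lines.append(
                f"co-senescence network: {len(self.network.edges)} edges over "
                f"{len(self.network.nodes)} cell types"
            )
            for e in self.network.edges:
                lines.append(f"  {e.cell_a} -- {e.cell_b}: |rho|={e.weight:.3f} p={e.p_value:.2e}")
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Overlaid ICSS histograms per cell type (matplotlib Axes)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for ct, sv in self.icss.items():
            ax.hist(sv.values, bins=30, alpha=0.5, label=ct)
        ax.set_xlabel("ICSS")
        ax.set_ylabel("units")
        ax.legend()
        return ax
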