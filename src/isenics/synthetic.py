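"""Ground-truth synthetic expression data with the structure ISENICS assumes.

The generator plants a binary senescence status per unit and per cell type
on top of log-normal baseline expression: senescent units up-regulate the
signature's positive genes by ``effect_up``, down-regulate its negative
genes by ``effect_down``, and up-regulate SASP genes by ``sasp_effect``.
Cell types may share a status vector (the co-senescence ground truth) or
senesce independently.  Pseudo-bulk mixtures at known fractions, and an
NNLS fraction re-estimator to validate them, round out the module.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .errors import ValidationError
from .io import ExpressionMatrix, GeneList, SignedGeneSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_celltype_profiles",
    "simulate_pseudobulk",
    "nnls_fractions",
    "auroc",
]


@dataclass
class SimConfig:
    """Study conditions of the simulated cohort.

    Defaults describe a deconvolved TPM-scale cohort: 200 samples, 100
    genes, 3 immune cell types sharing one senescence status (30% senescent
    samples), a 15-positive / 10-negative signature with two-fold effects,
    20 SASP genes co-varying two-fold with status, and log-normal noise with
    sd 0.5 on the natural-log scale around gene baselines drawn from
    N(2, 1) log-TPM.

    ``shared_status`` is either the string ``"all"`` (every cell type reuses
    one status vector), ``None``/``{}`` (independent statuses), or a mapping
    of cell-type pairs to booleans; pairs flagged True are merged into one
    shared-status component.
    """

    n_genes: int = 100
    n_units: int = 200
    n_celltypes: int = 3
    senescent_fraction: float = 0.3
    effect_up: float = 2.0
    effect_down: float = 2.0
    sasp_effect: float = 2.0
    n_pos: int = 15
    n_neg: int = 10
    n_sasp: int = 20
    shared_status: object = "all"
    noise_sd: float = 0.5
    baseline_log_mean_sd: tuple[float, float] = (2.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.senescent_fraction < 1:
            raise ValidationError("senescent_fraction must be in (0, 1)")
        if self.effect_up < 1 or self.effect_down < 1 or self.sasp_effect < 1:
            raise ValidationError("effect_up/effect_down must be >= 1 (1 = null)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.n_genes < self.n_pos + self.n_neg + self.n_sasp + 10:
            raise ValidationError(
                "n_genes must be >= n_pos + n_neg + n_sasp + 10 background genes"
            )
        if min(self.n_genes, self.n_units, self.n_celltypes, self.n_pos, self.n_neg) < 1:
            raise ValidationError("counts must be positive")

    @property
    def celltypes(self) -> list[str]:
        return [f"celltype{i + 1}" for i in range(self.n_celltypes)]


@dataclass
class SimTruth:
    """Planted ground truth behind a simulated cohort."""

    status: dict[str, np.ndarray]  # cell type -> per-unit senescent flag
    de_genes: dict[str, list[str]]  # positive / negative / sasp memberships
    fractions: np.ndarray | None = None  # units x cell types, rows sum to 1
    celltype_order: list[str] = field(default_factory=list)


def _status_components(config: SimConfig) -> list[set[str]]:
    """Union-find over shared_status pairs -> shared-status components."""
    cts = config.celltypes
    if config.shared_status == "all":
        return [set(cts)]
    parent = {ct: ct for ct in cts}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    pairs = config.shared_status or {}
    for (a, b), flag in dict(pairs).items():
        if flag:
            if a not in parent or b not in parent:
                raise ValidationError(f"shared_status names unknown cell type in ({a}, {b})")
            parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for ct in cts:
        comps.setdefault(find(ct), set()).add(ct)
    return list(comps.values())


def simulate_celltype_profiles(
    config: SimConfig,
) -> tuple[dict[str, ExpressionMatrix], SignedGeneSet, GeneList, SimTruth]:
    """Generate per-cell-type TPM matrices with a planted senescence program.

    Returns the matrices (shared sample ids across cell types), the signed
    signature, the SASP gene list, and the ground truth (statuses, planted
    memberships, and Dirichlet mixing fractions for pseudo-bulk).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    units = [f"S{i + 1:04d}" for i in range(config.n_units)]
    picked = rng.choice(config.n_genes, config.n_pos + config.n_neg + config.n_sasp,
                        replace=False)
    pos = [genes[i] for i in picked[: config.n_pos]]
    neg = [genes[i] for i in picked[config.n_pos : config.n_pos + config.n_neg]]
    sasp = [genes[i] for i in picked[config.n_pos + config.n_neg :]]
    signature = SignedGeneSet("SIMSEN", set(pos), set(neg))
    sasp_list = GeneList("SASP", set(sasp))

    n_sen = int(round(config.senescent_fraction * config.n_units))
    n_sen = min(max(n_sen, 1), config.n_units - 1)
    comp_status: dict[str, np.ndarray] = {}
    for comp in _status_components(config):
        status = np.zeros(config.n_units, dtype=bool)
        status[rng.choice(config.n_units, n_sen, replace=False)] = True
        for ct in comp:
            comp_status[ct] = status

    mu, sd = config.baseline_log_mean_sd
    gene_pos = {g: i for i, g in enumerate(genes)}
    pos_idx = np.array([gene_pos[g] for g in pos])
    neg_idx = np.array([gene_pos[g] for g in neg])
    sasp_idx = np.array([gene_pos[g] for g in sasp])

    profiles: dict[str, ExpressionMatrix] = {}
    for ct in config.celltypes:
        baseline = rng.normal(mu, sd, size=config.n_genes)
        log_expr = baseline[:, None] + rng.normal(0.0, config.noise_sd,
                                                  size=(config.n_genes, config.n_units))
        expr = np.exp(log_expr)
        sen = comp_status[ct]
        expr[np.ix_(pos_idx, np.flatnonzero(sen))] *= config.effect_up
        expr[np.ix_(neg_idx, np.flatnonzero(sen))] /= config.effect_down
        expr[np.ix_(sasp_idx, np.flatnonzero(sen))] *= config.sasp_effect
        profiles[ct] = ExpressionMatrix(list(genes), list(units), expr, scale="tpm")

    fractions = rng.dirichlet(np.ones(config.n_celltypes), size=config.n_units)
    truth = SimTruth(
        status={ct: comp_status[ct].copy() for ct in config.celltypes},
        de_genes={"positive": pos, "negative": neg, "sasp": sasp},
        fractions=fractions,
        celltype_order=config.celltypes,
    )
    return profiles, signature, sasp_list, truth


def simulate_pseudobulk(
    profiles: dict[str, ExpressionMatrix], fractions: np.ndarray
) -> ExpressionMatrix:
    """Mix per-cell-type profiles into per-sample pseudo-bulk at known fractions.

    ``fractions`` is units x cell types (column order = profile dict order);
    each row must be non-negative and sum to 1 within 1e-6.
    """
    cts = list(profiles)
    first = profiles[cts[0]]
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (first.n_units, len(cts)):
        raise ValidationError(
            f"fractions must be (n_units={first.n_units}) x (n_celltypes={len(cts)})"
        )
    if np.any(fractions < 0):
        raise ValidationError("fractions must be non-negative")
    if np.any(np.abs(fractions.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("per-sample fractions must sum to 1 (tolerance 1e-6)")
    for ct in cts[1:]:
        if profiles[ct].gene_ids != first.gene_ids or profiles[ct].unit_ids != first.unit_ids:
            raise ValidationError("profiles must share gene and unit spaces")
    bulk = np.zeros_like(first.values)
    for c, ct in enumerate(cts):
        bulk += profiles[ct].values * fractions[:, c][None, :]
    return ExpressionMatrix(list(first.gene_ids), list(first.unit_ids), bulk, scale="tpm")


def nnls_fractions(bulk: ExpressionMatrix, signature: dict[str, np.ndarray]) -> np.ndarray:
    """Re-estimate cell-type fractions per sample by non-negative least squares.

    ``signature`` maps cell type -> mean expression vector over the bulk
    matrix's gene space.  Returns units x cell types, rows renormalised to
    sum 1.  A reference stand-in used to validate pseudo-bulk mixtures; the
    model proper consumes externally deconvolved profiles.
    """
    cts = list(signature)
    if len(cts) < 2:
        raise ValidationError("need >= 2 cell types")
    sig = np.column_stack([np.asarray(signature[ct], dtype=float) for ct in cts])
    if sig.shape[0] != bulk.n_genes:
        raise ValidationError("signature vectors must match the bulk gene space")
    if sig.shape[0] < sig.shape[1]:
        raise ValidationError("need at least as many shared genes as cell types")
    if np.linalg.matrix_rank(sig) < sig.shape[1]:
        import warnings

        warnings.warn("rank-deficient signature matrix; NNLS solution may be non-unique",
                      stacklevel=2)
    out = np.zeros((bulk.n_units, len(cts)))
    for j in range(bulk.n_units):
        coef, _ = scipy.optimize.nnls(sig, bulk.values[:, j])
        total = coef.sum()
        out[j] = coef / total if total > 0 else np.full(len(cts), 1.0 / len(cts))
    return out


def auroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-statistic AUROC of scores against a boolean truth vector."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n1 = int(truth.sum())
    n0 = len(truth) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("auroc needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[truth].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
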