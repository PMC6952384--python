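"""Cross-dataset merging, gene scaling, and batch-effect removal.

Batch correction follows the parametric empirical-Bayes location/scale
model: gene-wise standardisation against a least-squares grand mean,
method-of-moments priors across genes (normal prior on the additive batch
effect gamma, inverse-gamma prior on the multiplicative effect delta^2),
iterative shrinkage of the per-(batch, gene) estimates to their posterior
means, and back-transformation.  No reference batch, covariates, or
non-parametric priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


def intersect_and_merge(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge datasets on the intersection of their gene IDs.

    Gene order in the result is sorted; per-dataset batch labels are
    preserved and sample counts add up.  Raises if the gene intersection is
    empty (naming the offending datasets) or sample IDs collide.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        sizes = ", ".join(f"dataset {i} ({m.n_genes} genes)" for i, m in enumerate(matrices))
        raise ValueError(f"empty gene intersection across inputs: {sizes}")
    genes = sorted(common)
    seen: set[str] = set()
    for i, m in enumerate(matrices):
        clash = seen & set(m.sample_ids)
        if clash:
            raise ValueError(f"duplicate sample IDs across datasets (dataset {i}): {sorted(clash)[:5]}")
        seen |= set(m.sample_ids)
    values = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    batch = pd.concat([m.batch for m in matrices])
    return ExpressionMatrix(values, batch)


def scale_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene row to mean 0 and unit sample SD (ddof = 1).

    Zero-variance rows cannot be scaled; they are dropped with a warning.
    """
    if m.n_samples < 2:
        raise ValueError("gene scaling needs at least 2 samples")
    sd = m.values.std(axis=1, ddof=1)
    constant = sd <= 0
    values = m.values
    if constant.any():
        logger.warning("dropping %d constant gene rows before scaling", int(constant.sum()))
        values = values.loc[~constant]
        sd = sd.loc[~constant]
    scaled = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(scaled, m.batch)


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch model (one row per batch)."""

    gamma_star: pd.DataFrame        # batch x gene additive effects (posterior)
    delta2_star: pd.DataFrame       # batch x gene multiplicative effects (posterior)
    grand_mean: pd.Series           # per-gene least-squares grand mean
    pooled_var: pd.Series           # per-gene pooled variance
    priors: pd.DataFrame            # per-batch hyperparameters (gamma_bar, tau2, a, b)
    n_iter: pd.Series               # EB iterations per batch

    def __post_init__(self) -> None:
        if (self.delta2_star.to_numpy() <= 0).any():
            raise ValueError("posterior delta^2 must be positive")


def _eb_priors(gamma_hat: np.ndarray, delta2_hat: np.ndarray):
    """Method-of-moments hyperparameters of the parametric priors."""
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    m = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1)
    a = (2.0 * s2 + m ** 2) / s2
    b = (m * s2 + m ** 3) / s2
    return gamma_bar, tau2, a, b


def _eb_solve(z: np.ndarray, gamma_hat, delta2_hat, gamma_bar, tau2, a, b,
              tol: float = 1e-4, max_iter: int = 100):
    """Iterate the coupled posterior-mean equations for one batch."""
    n = z.shape[1]
    gamma = gamma_hat.copy()
    delta2 = delta2_hat.copy()
    for it in range(1, max_iter + 1):
        gamma_new = (n * tau2 * gamma_hat + delta2 * gamma_bar) / (n * tau2 + delta2)
        resid2 = ((z - gamma_new[:, None]) ** 2).sum(axis=1)
        delta2_new = (0.5 * resid2 + b) / (n / 2.0 + a - 1.0)
        change = max(np.abs(gamma_new - gamma).max(), np.abs(delta2_new - delta2).max())
        gamma, delta2 = gamma_new, delta2_new
        if change < tol:
            break
    return gamma, delta2, it


def combat_correct(
    m: ExpressionMatrix,
    parametric: bool = True,
    allow_single_batch: bool = False,
) -> tuple[ExpressionMatrix, BatchModel]:
    """Remove additive and multiplicative batch effects (parametric EB).

    Every batch must contain at least 2 samples.  With a single batch the
    call raises unless ``allow_single_batch`` is set, in which case the
    data pass through unchanged.
    """
    if not parametric:
        raise NotImplementedError("only parametric priors are implemented")
    counts = m.batch.value_counts()
    batches = sorted(counts.index)
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"batches with fewer than 2 samples: {sorted(small.index)}; "
            "pass them through separately or exclude them"
        )
    x = m.values.to_numpy()
    genes, samples = m.gene_ids, m.sample_ids
    if len(batches) == 1:
        if not allow_single_batch:
            raise ValueError("single-batch input: nothing to correct (set allow_single_batch)")
        trivial = BatchModel(
            gamma_star=pd.DataFrame(0.0, index=batches, columns=genes),
            delta2_star=pd.DataFrame(1.0, index=batches, columns=genes),
            grand_mean=m.values.mean(axis=1),
            pooled_var=m.values.var(axis=1, ddof=0),
            priors=pd.DataFrame(index=batches, columns=["gamma_bar", "tau2", "a", "b"], dtype=float),
            n_iter=pd.Series(0, index=batches),
        )
        return m.copy(), trivial

    n_total = m.n_samples
    masks = {b: (m.batch == b).to_numpy() for b in batches}
    batch_means = np.stack([x[:, masks[b]].mean(axis=1) for b in batches])
    weights = np.array([counts[b] / n_total for b in batches])
    grand_mean = weights @ batch_means
    fitted = np.zeros_like(x)
    for i, b in enumerate(batches):
        fitted[:, masks[b]] = batch_means[i][:, None]
    pooled_var = ((x - fitted) ** 2).mean(axis=1)
    if (pooled_var <= 0).any():
        raise ValueError("genes with zero pooled variance cannot be standardized")
    z = (x - grand_mean[:, None]) / np.sqrt(pooled_var)[:, None]

    gamma_star = np.empty((len(batches), len(genes)))
    delta2_star = np.empty_like(gamma_star)
    priors = []
    iters = []
    for i, b in enumerate(batches):
        zb = z[:, masks[b]]
        gamma_hat = zb.mean(axis=1)
        delta2_hat = zb.var(axis=1, ddof=1)
        gamma_bar, tau2, a, bb = _eb_priors(gamma_hat, delta2_hat)
        g_star, d2_star, it = _eb_solve(zb, gamma_hat, delta2_hat, gamma_bar, tau2, a, bb)
        gamma_star[i], delta2_star[i] = g_star, d2_star
        priors.append({"gamma_bar": gamma_bar, "tau2": tau2, "a": a, "b": bb})
        iters.append(it)

    adjusted = np.empty_like(x)
    for i, b in enumerate(batches):
        adjusted[:, masks[b]] = (z[:, masks[b]] - gamma_star[i][:, None]) / np.sqrt(
            delta2_star[i]
        )[:, None]
    adjusted = adjusted * np.sqrt(pooled_var)[:, None] + grand_mean[:, None]

    model = BatchModel(
        gamma_star=pd.DataFrame(gamma_star, index=batches, columns=genes),
        delta2_star=pd.DataFrame(delta2_star, index=batches, columns=genes),
        grand_mean=pd.Series(grand_mean, index=genes),
        pooled_var=pd.Series(pooled_var, index=genes),
        priors=pd.DataFrame(priors, index=batches),
        n_iter=pd.Series(iters, index=batches),
    )
    corrected = ExpressionMatrix(pd.DataFrame(adjusted, index=genes, columns=samples), m.batch)
    return corrected, model
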