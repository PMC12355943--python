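"""Model-selection metrics (BIC, NRMSE, PUI) and the variant-choice rule.

Four variants compete per dataset: CA/DA route combination crossed with the
SD/IT death mechanism.  NRMSE and BIC carry the primary ranking; when
candidates are comparable, the parameter uncertainty index (PUI) breaks the
tie, and remaining ties go to the variant with fewer free parameters.  BIC
values are only comparable within one dataset, which the API enforces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariantMetrics",
    "n_free_parameters",
    "bic",
    "nrmse",
    "pui",
    "choose_variant",
]


def n_free_parameters(
    combination: str, death: str, n_routes: int, include_hb: bool = False
) -> int:
    """Free TKTD parameter count of a variant.

    CA shares one dominant rate constant and adds one weight per route
    beyond the first: ``N + 2``.  DA has route-specific rate constants:
    ``2N + 1``.  Both collapse to 3 for a single route.  ``include_hb``
    adds the background hazard (the "+1").
    """
    if n_routes < 1:
        raise ValueError("n_routes must be >= 1")
    if combination not in ("CA", "DA"):
        raise ValueError(f"unknown combination {combination!r}")
    if death not in ("SD", "IT"):
        raise ValueError(f"unknown death mechanism {death!r}")
    k = n_routes + 2 if combination == "CA" else 2 * n_routes + 1
    return k + (1 if include_hb else 0)


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion ``k*ln(n) - 2*logL`` (natural logs)."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    return k * np.log(n) - 2.0 * log_likelihood


def nrmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-square error normalized by the mean observed count.

    ``(1/mean(y)) * sqrt(mean((y - yhat)^2))`` — a fraction; multiply by 100
    to report percent.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("observed and predicted must be equal-length and non-empty")
    ybar = y.mean()
    if ybar <= 0:
        raise ValueError("mean observed count must be > 0")
    return float(np.sqrt(np.mean((y - yhat) ** 2)) / ybar)


def pui(quantiles: pd.DataFrame | dict) -> float:
    """Parameter uncertainty index: mean ``log10(Q97.5/Q2.5)`` across the
    free TKTD parameters (the background hazard must already be excluded).

    Accepts a frame indexed by parameter with columns ``q2.5``/``q97.5`` or a
    mapping name -> (q2.5, q97.5).
    """
    if isinstance(quantiles, pd.DataFrame):
        lo = quantiles["q2.5"].to_numpy(dtype=float)
        hi = quantiles["q97.5"].to_numpy(dtype=float)
    else:
        pairs = list(quantiles.values())
        lo = np.asarray([p[0] for p in pairs], dtype=float)
        hi = np.asarray([p[1] for p in pairs], dtype=float)
    if lo.size == 0:
        raise ValueError("need at least one parameter")
    if np.any(lo <= 0) or np.any(hi <= 0):
        raise ValueError("quantiles must be > 0")
    return float(np.mean(np.log10(hi / lo)))


@dataclass(frozen=True)
class VariantMetrics:
    """Selection metrics of one variant fitted to one dataset."""

    variant: str  # e.g. "CA-SD"
    k: int
    n: int
    bic: float
    nrmse: float
    pui: float
    dataset_id: str = "default"
    nrmse_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.nrmse < 0 or self.pui < 0:
            raise ValueError("nrmse and pui must be >= 0")


def choose_variant(
    metrics: list[VariantMetrics],
    nrmse_tol: float | None = None,
    bic_tol: float = 2.0,
) -> tuple[VariantMetrics, list[str]]:
    """Pick the preferred variant and return it with a rationale trail.

    Candidates are first screened on NRMSE and BIC: every variant whose
    NRMSE is within tolerance of the best (overlapping 95% NRMSE intervals
    when available, else ``nrmse_tol``, default 0.02 absolute) and whose BIC
    is within ``bic_tol`` of the best stays in the running.  Among
    comparable candidates the lowest PUI wins; remaining ties go to the
    fewest free parameters.  All metrics must come from one dataset.
    """
    if len(metrics) < 2:
        raise ValueError("need metrics for at least two variants")
    ids = {m.dataset_id for m in metrics}
    if len(ids) > 1:
        raise ValueError(
            f"BIC/NRMSE ranking across different datasets is not meaningful: {sorted(ids)}"
        )
    rationale: list[str] = []
    best_nrmse = min(m.nrmse for m in metrics)
    best_bic = min(m.bic for m in metrics)

    def nrmse_comparable(m: VariantMetrics) -> bool:
        ref = next(x for x in metrics if x.nrmse == best_nrmse)
        if m.nrmse_interval is not None and ref.nrmse_interval is not None:
            return m.nrmse_interval[0] <= ref.nrmse_interval[1] and ref.nrmse_interval[0] <= m.nrmse_interval[1]
        tol = 0.02 if nrmse_tol is None else nrmse_tol
        return m.nrmse <= best_nrmse + tol

    candidates = [m for m in metrics if nrmse_comparable(m) and m.bic <= best_bic + bic_tol]
    if not candidates:
        candidates = [min(metrics, key=lambda m: (m.nrmse, m.bic))]
    if len(candidates) == 1:
        winner = candidates[0]
        rationale.append(
            f"{winner.variant} is best on NRMSE ({winner.nrmse:.4f}) and BIC "
            f"({winner.bic:.2f}); no comparable competitor."
        )
        return winner, rationale
    rationale.append(
        "Comparable on NRMSE/BIC: " + ", ".join(m.variant for m in candidates)
        + "; considering PUI."
    )
    best_pui = min(m.pui for m in candidates)
    by_pui = [m for m in candidates if m.pui <= best_pui + 1e-12]
    if len(by_pui) == 1:
        winner = by_pui[0]
        rationale.append(f"{winner.variant} chosen for lowest PUI ({winner.pui:.3f}).")
        return winner, rationale
    winner = min(by_pui, key=lambda m: m.k)
    rationale.append(
        f"PUI tied; {winner.variant} chosen for fewest free parameters (k={winner.k})."
    )
    return winner, rationale
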