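"""Evidence between model variants and posterior parameter structure.

The Bayes Ratio for models r and i is the ratio of the *maximum* likelihood
attained over the converged segments of their Markov chains,

    B_ri = Max_k P(Y | theta_k, M_r) / Max_k P(Y | theta_k, M_i),

computed separately for each observed (group, measurand) series with that
series' own N_obs in the likelihood exponent.  B between 1 and 3 is weak,
3-20 positive, 20-150 strong and above 150 very strong evidence for model
r; B below 1 favors model i.

Posterior parameter structure is summarized by pairwise Pearson
correlations of the log10 parameters across the retained ensemble (pairs
with |r| above 0.95 are flagged practically non-identifiable, e.g. a
secretion rate against its assay scale) and by log-ratio statistics of
named parameter groups (e.g. the deactivation share
(a4+a5)/(kp3a+kd5a+a4+a5)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_core import SchemaError, ValidationError
from .inference import ChainArchive, PosteriorEnsemble, log_likelihood

__all__ = [
    "EVIDENCE_BANDS",
    "EvidenceReport",
    "max_log_likelihood",
    "bayes_ratio",
    "classify_evidence",
    "identifiability",
    "RatioStats",
    "ratio_stats",
    "evidence_report",
]

EVIDENCE_BANDS = (
    (1.0, 3.0, "weak"),
    (3.0, 20.0, "positive"),
    (20.0, 150.0, "strong"),
    (150.0, math.inf, "very_strong"),
)


def _as_chain_list(chains) -> list[ChainArchive]:
    if isinstance(chains, ChainArchive):
        return [chains]
    return list(chains)


def max_log_likelihood(chains, measurand_key: str, burn: int = 0) -> float:
    """Max per-measurand log-likelihood over the converged steps of chains.

    ``measurand_key`` is ``"group:measurand"`` as archived by the
    calibration problem; the measurand's own observation count enters the
    likelihood exponent.
    """
    chains = _as_chain_list(chains)
    sse_key = f"sse:{measurand_key}"
    best = -np.inf
    for chain in chains:
        if sse_key not in chain.extras:
            raise SchemaError(f"measurand {measurand_key!r} absent from chain archive")
        n_obs = chain.meta.get("n_obs", {}).get(measurand_key)
        if n_obs is None:
            raise SchemaError(f"observation count for {measurand_key!r} missing from meta")
        sse = chain.extras[sse_key][burn:]
        if sse.size == 0:
            raise ValidationError("burn leaves no converged steps")
        best = max(best, log_likelihood(float(sse.min()), int(n_obs)))
    return float(best)


def bayes_ratio(chains_r, chains_i, measurand_key: str, burn: int = 0) -> float:
    """Evidence for model r over model i on one (group, measurand) series."""
    log_b = (max_log_likelihood(chains_r, measurand_key, burn)
             - max_log_likelihood(chains_i, measurand_key, burn))
    return float(np.exp(log_b))


def classify_evidence(B: float) -> str:
    """Band a Bayes Ratio into the standard evidence categories.

    ``B`` in [1, 3] is weak, (3, 20] positive, (20, 150] strong, above 150
    very strong; below 1 the evidence favors the other model.  The lower
    boundary is closed (B = 1 classifies as weak).
    """
    if not B > 0:
        raise ValidationError(f"Bayes Ratio must be positive, got {B!r}")
    if B < 1.0:
        return "favors_other"
    for lo, hi, label in EVIDENCE_BANDS:
        if lo <= B <= hi:
            return label
    return "very_strong"


@dataclass
class EvidenceReport:
    """Per-measurand Bayes Ratios of one model pair, with categories."""

    model_r: str
    model_i: str
    ratios: Mapping[str, float]
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.categories:
            self.categories = {k: classify_evidence(v) for k, v in self.ratios.items()}

    def to_table(self) -> str:
        lines = [f"{'series':<32s} {'Bayes Ratio':>12s}  category",
                 "-" * 60]
        for key, value in self.ratios.items():
            lines.append(f"{key:<32s} {value:>12.4g}  {self.categories[key]}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model_r": self.model_r, "model_i": self.model_i,
            "ratios": dict(self.ratios), "categories": dict(self.categories),
        }


def evidence_report(chains_r, chains_i, burn: int = 0,
                    model_r: str = "r", model_i: str = "i") -> EvidenceReport:
    """Bayes Ratios for every measurand series archived in both chain sets."""
    chains_r = _as_chain_list(chains_r)
    chains_i = _as_chain_list(chains_i)
    keys_r = {k[4:] for k in chains_r[0].extras if k.startswith("sse:") and k != "sse:total"}
    keys_i = {k[4:] for k in chains_i[0].extras if k.startswith("sse:") and k != "sse:total"}
    ratios = {key: bayes_ratio(chains_r, chains_i, key, burn)
              for key in sorted(keys_r & keys_i)}
    return EvidenceReport(model_r=model_r, model_i=model_i, ratios=ratios)


# ---------------------------------------------------------------------------
# Posterior parameter structure
# ---------------------------------------------------------------------------


def identifiability(ens: PosteriorEnsemble, threshold: float = 0.95):
    """Pairwise Pearson correlations of log10 parameters; flag |r| > threshold.

    Returns ``(names, corr_matrix, flagged_pairs)``.  A parameter that is
    constant across the ensemble has undefined correlations; its row and
    column are reported as NaN and it is never flagged.
    """
    if len(ens) < 10:
        raise ValidationError("identifiability needs an ensemble of at least 10 samples")
    names = list(ens.meta.get("free_names", [f"theta{j}" for j in range(ens.thetas.shape[1])]))
    scales = ens.meta.get("scales", ["log10"] * len(names))
    columns = np.empty((len(ens), len(names)))
    for j, scale in enumerate(scales):
        col = ens.thetas[:, j]
        columns[:, j] = col  # sampling coordinates are already log10/linear
    sd = columns.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(columns, rowvar=False)
    corr = np.atleast_2d(corr)
    constant = sd == 0
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    flagged = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if np.isfinite(corr[a, b]) and abs(corr[a, b]) > threshold:
                flagged.append((names[a], names[b], float(corr[a, b])))
    return names, corr, flagged


@dataclass(frozen=True)
class RatioStats:
    """Distribution summary of log10(numerator/denominator) over an ensemble."""

    mean_log10: float
    sd_log10: float
    exceedance: Mapping[float, float]  # threshold (on the plain ratio) -> P(ratio > t)
    n_used: int
    n_excluded: int


def ratio_stats(ens: PosteriorEnsemble, numerator: Sequence[str] | str,
                denominator: Sequence[str] | str,
                exceedance_thresholds: Sequence[float] = ()) -> RatioStats:
    """Per-sample ratio of summed parameter groups, summarized in log10.

    ``numerator`` and ``denominator`` are parameter names (or lists of
    names; a list is summed per sample before dividing), e.g.
    ``ratio_stats(ens, "a4", "a5")`` for the constitutive-vs-feedback
    deactivation balance, or
    ``ratio_stats(ens, ["a4", "a5"], ["kp3a_hDCT", "kd5a_hDCT", "a4", "a5"],
    [0.5])`` for the deactivated cell-fate share.  Samples with a zero
    denominator are excluded and counted.
    """
    num_names = [numerator] if isinstance(numerator, str) else list(numerator)
    den_names = [denominator] if isinstance(denominator, str) else list(denominator)
    num = np.sum([ens.parameter_column(n) for n in num_names], axis=0)
    den = np.sum([ens.parameter_column(n) for n in den_names], axis=0)
    ok = den > 0
    n_excluded = int((~ok).sum())
    num, den = num[ok], den[ok]
    if num.size == 0:
        raise ValidationError("all samples excluded (zero denominator)")
    ratio = num / den
    log_ratio = np.log10(np.maximum(ratio, 1e-300))
    exceedance = {float(t): float(np.mean(ratio > t)) for t in exceedance_thresholds}
    return RatioStats(
        mean_log10=float(log_ratio.mean()),
        sd_log10=float(log_ratio.std(ddof=1)) if log_ratio.size > 1 else 0.0,
        exceedance=exceedance, n_used=int(num.size), n_excluded=n_excluded,
    )
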