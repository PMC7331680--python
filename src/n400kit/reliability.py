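"""Data-quality metrics and the per-subject summary pipeline.

The standardised measurement error (SME) quantifies single-subject data
quality: trials are resampled with replacement within each condition (at
the original accepted counts), the 300-800 ms mean amplitude of the
bootstrap difference ERP is recorded, and the SME is the standard
deviation of that score over bootstraps.

``run_pipeline`` ties everything together for a cohort: unconstrained
decoding with permutation inference, time-resolved decoding with TFCE
correction, the univariate cluster analysis, and SME — producing a
per-subject Yes/No summary table with a totals row (e.g. "13/20").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import ClassifierSpec, decode_subject
from .epochs import EpochSet
from .errors import DegenerateNullError, ValidationError
from .localized import TfceSpec, time_resolved_inference
from .univariate import RoiSpec, univariate_n400

__all__ = [
    "SmeResult",
    "SubjectSummary",
    "sme_bootstrap",
    "sme_map",
    "spearman",
    "summarize_subjects",
    "PipelineConfig",
    "run_pipeline",
]


@dataclass
class SmeResult:
    """Per-channel SME (µV) plus the scalp mean."""

    channels: tuple[str, ...]
    sme: np.ndarray
    n_boot: int
    window: tuple[float, float]
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.sme))

    def roi_mean(self, channels) -> float:
        idx = [self.channels.index(c) for c in channels]
        return float(np.mean(self.sme[idx]))


@dataclass
class SubjectSummary:
    """Per-subject detection flags and quality metrics."""

    subject_id: str
    unconstrained_mvpa: bool
    time_resolved_mvpa: bool
    univariate_n400: bool
    accuracy: float
    effect_size: float | None
    p_rank: float
    sme_mean: float
    n400_area: float


def _window_scores(epochs: EpochSet, window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial per-channel mean amplitude over the window, split by
    condition (accepted trials only)."""
    mask = (epochs.times >= window[0] - 1e-9) & (epochs.times <= window[1] + 1e-9)
    if not mask.any():
        raise ValidationError(f"epochs do not cover the window {window}")
    scores = epochs.voltages[:, :, mask].mean(axis=2)  # trials x channels
    keep_c = (epochs.condition == "congruent") & ~epochs.rejected
    keep_i = (epochs.condition == "incongruent") & ~epochs.rejected
    if keep_c.sum() < 2 or keep_i.sum() < 2:
        raise ValidationError("need >= 2 accepted trials per condition for the SME")
    return scores[keep_c], scores[keep_i]


def sme_map(
    epochs: EpochSet,
    window: tuple[float, float] = (300.0, 800.0),
    n_boot: int = 10000,
    seed: int = 0,
) -> SmeResult:
    """Bootstrap SME for every channel.

    Each bootstrap draws, with replacement, as many congruent and
    incongruent accepted trials as were accepted, forms the difference
    ERP's mean amplitude over the window, and the SME per channel is the
    SD of that quantity across bootstraps (shared resampling draws across
    channels).
    """
    sc, si = _window_scores(epochs, window)
    rng = np.random.default_rng(seed)
    n_c, n_i = sc.shape[0], si.shape[0]
    idx_c = rng.integers(0, n_c, size=(n_boot, n_c))
    idx_i = rng.integers(0, n_i, size=(n_boot, n_i))
    boots = sc[idx_c].mean(axis=1) - si[idx_i].mean(axis=1)  # n_boot x channels
    return SmeResult(
        channels=epochs.channels,
        sme=boots.std(axis=0, ddof=1),
        n_boot=n_boot,
        window=window,
        seed=seed,
    )


def sme_bootstrap(
    epochs: EpochSet,
    channel: str,
    window: tuple[float, float] = (300.0, 800.0),
    n_boot: int = 10000,
    seed: int = 0,
) -> float:
    """Bootstrap SME (µV) of the windowed difference-ERP amplitude for one channel."""
    ci = epochs.channel_index(channel)
    sc, si = _window_scores(epochs, window)
    rng = np.random.default_rng(seed)
    n_c, n_i = sc.shape[0], si.shape[0]
    idx_c = rng.integers(0, n_c, size=(n_boot, n_c))
    idx_i = rng.integers(0, n_i, size=(n_boot, n_i))
    boots = sc[idx_c, ci].mean(axis=1) - si[idx_i, ci].mean(axis=1)
    return float(boots.std(ddof=1))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length inputs with >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateNullError("constant input has no defined rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def summarize_subjects(summaries: list) -> pd.DataFrame:
    """Per-subject Yes/No table with a totals row (e.g. "13/20")."""
    if not summaries:
        raise ValidationError("no subject summaries provided")
    rows = []
    for s in summaries:
        for attr in ("unconstrained_mvpa", "time_resolved_mvpa", "univariate_n400"):
            if getattr(s, attr) is None:
                raise ValidationError(f"subject {s.subject_id}: missing analysis '{attr}'")
        rows.append(
            {
                "subject_id": s.subject_id,
                "unconstrained_mvpa": "Yes" if s.unconstrained_mvpa else "No",
                "time_resolved_mvpa": "Yes" if s.time_resolved_mvpa else "No",
                "univariate_n400": "Yes" if s.univariate_n400 else "No",
                "accuracy": s.accuracy,
                "effect_size": s.effect_size,
                "p_rank": s.p_rank,
                "sme_mean_uV": s.sme_mean,
                "n400_area_uVms": s.n400_area,
            }
        )
    df = pd.DataFrame(rows)
    n = len(summaries)
    totals = {
        "subject_id": "Total",
        "unconstrained_mvpa": f"{(df['unconstrained_mvpa'] == 'Yes').sum()}/{n}",
        "time_resolved_mvpa": f"{(df['time_resolved_mvpa'] == 'Yes').sum()}/{n}",
        "univariate_n400": f"{(df['univariate_n400'] == 'Yes').sum()}/{n}",
        "accuracy": np.nan, "effect_size": np.nan, "p_rank": np.nan,
        "sme_mean_uV": np.nan, "n400_area_uVms": np.nan,
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


@dataclass(frozen=True)
class PipelineConfig:
    """Scaled defaults for the full per-subject pipeline.

    The reduced permutation/bootstrap counts keep a 20-subject cohort
    tractable on one CPU; set ``n_perm=1000``/``n_boot=10000`` for
    full-scale runs.
    """

    clf: ClassifierSpec = field(default_factory=ClassifierSpec)
    roi: RoiSpec = field(default_factory=RoiSpec)
    tfce: TfceSpec = field(default_factory=TfceSpec)
    n_perm: int = 100
    n_boot: int = 1000
    n_sim_cluster: int = 1000
    halfwidth: int = 5
    alpha: float = 0.05
    reject_threshold: float = 200.0


def run_pipeline(
    cohort: list,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Run all three analyses plus SME on a cohort of EpochSets.

    ``cohort`` is a list of :class:`EpochSet` (or paths loadable with
    :func:`n400kit.epochs.load_epochs`).  Rejection masks are honoured by
    the univariate branch and by the SME; decoding uses all trials.
    Returns the summary table (with totals row) and the list of
    per-subject result dicts.  Deterministic given ``seed``.
    """
    from .epochs import load_epochs
    from .preprocessing import reject_artifacts

    cfg = config if config is not None else PipelineConfig()
    summaries = []
    details = []
    for k, item in enumerate(cohort):
        epochs = item if isinstance(item, EpochSet) else load_epochs(item)
        sid = epochs.subject_id or f"S{k + 1:02d}"
        sub_seed = int(np.random.SeedSequence((seed, k)).generate_state(1)[0])
        if not epochs.rejected.any():
            roi_scope = [c for c in cfg.roi.channels if c in epochs.channels]
            if len(roi_scope) == len(cfg.roi.channels):
                epochs = reject_artifacts(epochs, cfg.reject_threshold, tuple(roi_scope))
        dec = decode_subject(
            epochs, cfg.clf, n_perm=cfg.n_perm, seed=sub_seed, alpha=cfg.alpha
        )
        tr = time_resolved_inference(
            epochs, cfg.clf, halfwidth=cfg.halfwidth, n_perm=cfg.n_perm,
            seed=sub_seed + 1, tfce=cfg.tfce, alpha=cfg.alpha,
        )
        uni = univariate_n400(
            epochs, cfg.roi, alpha=cfg.alpha, n_sim=cfg.n_sim_cluster, seed=sub_seed + 2
        )
        sme = sme_map(epochs, window=cfg.roi.n400_window, n_boot=cfg.n_boot, seed=sub_seed + 3)
        summaries.append(
            SubjectSummary(
                subject_id=sid,
                unconstrained_mvpa=bool(dec.significant),
                time_resolved_mvpa=tr.significant_any,
                univariate_n400=uni["clusters"].significant,
                accuracy=dec.accuracy,
                effect_size=dec.effect_size,
                p_rank=dec.p_rank,
                sme_mean=sme.mean,
                n400_area=uni["area_uVms"],
            )
        )
        details.append({"decoding": dec, "time_resolved": tr, "univariate": uni, "sme": sme})
    return summarize_subjects(summaries), details
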