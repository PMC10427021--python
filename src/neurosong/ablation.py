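"""Virtual-lesion analysis of linear decoding models.

Anatomically and functionally defined electrode sets are removed from the
inputs of per-bin linear decoders and the change in test-set prediction
accuracy (delta r per spectrogram bin, ablated minus baseline) measures
how much unique stimulus information the set carried.  The baseline uses
all significant electrodes; splits and seeds are shared between baseline
and every ablation so deltas reflect electrode removal only.  Linear
models are used throughout so a removed representation cannot be
re-synthesized nonlinearly from the remaining electrodes.

Interpretation rule: a significant accuracy drop marks a set as carrying
*unique* information; no significant drop, for electrodes whose STRFs are
individually significant, marks the information as *redundant* (encoded
elsewhere too).  Functional sets may overlap, which blocks cross-set
uniqueness claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HfaMatrix, Spectrogram
from .decoding import DecoderConfig, _fit_predict, decoding_split
from .encoding import pearson_r
from .features import apply_scaler, build_lag_matrix, fit_feature_scaler

__all__ = [
    "ElectrodeSet",
    "define_sets",
    "per_bin_decoder_r",
    "AblationResult",
    "ablate_and_decode",
    "ablation_anova",
    "classify_information",
]

logger = logging.getLogger(__name__)

REGIONS = ("STG", "SMC", "IFG", "other")
COMPONENTS = ("onset", "sustained", "late_onset", "rhythmic")
LATERALITIES = ("bilateral", "L", "R")


@dataclass
class ElectrodeSet:
    name: str
    kind: str  # anatomical | functional
    members: list[str]
    laterality: str = "bilateral"


def define_sets(table: pd.DataFrame) -> list[ElectrodeSet]:
    """Default ablation catalog from an electrode table.

    Anatomical: {STG, SMC, IFG, other} x {bilateral, L, R} plus whole
    hemispheres L and R (14 candidates); functional: the four component
    flags x {bilateral, L, R} (12 candidates).  Functional membership
    comes from boolean columns onset/sustained/late_onset/rhythmic.
    Empty sets are dropped with a warning.
    """
    sets: list[ElectrodeSet] = []

    def lat_mask(lat: str) -> pd.Series:
        if lat == "bilateral":
            return pd.Series(True, index=table.index)
        return table["hemisphere"] == lat

    for hemi in ("L", "R"):
        members = table.loc[table["hemisphere"] == hemi, "electrode_id"].tolist()
        sets.append(ElectrodeSet(f"hemisphere_{hemi}", "anatomical", members, hemi))
    for region in REGIONS:
        for lat in LATERALITIES:
            mask = (table["region"] == region) & lat_mask(lat)
            sets.append(ElectrodeSet(f"{region}_{lat}", "anatomical",
                                     table.loc[mask, "electrode_id"].tolist(), lat))
    for comp in COMPONENTS:
        if comp not in table.columns:
            continue
        for lat in LATERALITIES:
            mask = table[comp].astype(bool) & lat_mask(lat)
            sets.append(ElectrodeSet(f"{comp}_{lat}", "functional",
                                     table.loc[mask, "electrode_id"].tolist(), lat))
    kept = []
    for s in sets:
        if not s.members:
            logger.warning("dropping empty electrode set %s", s.name)
        else:
            kept.append(s)
    return kept


def per_bin_decoder_r(
    hfa_values: np.ndarray,
    target: Spectrogram,
    cfg: DecoderConfig,
    fixed_test: tuple[int, int],
    vocal_mask: np.ndarray,
    split_seeds: list[int],
    hyper: float | None = None,
) -> np.ndarray:
    """Test-set Pearson r of one linear decoder per target bin.

    Accuracy is averaged over the splits given by ``split_seeds`` (shared
    across ablations so deltas isolate the electrode removal).
    """
    hyper = cfg.strf_cfg.learning_rate if hyper is None else hyper
    n_frames = hfa_values.shape[0]
    base = build_lag_matrix(hfa_values, np.zeros(n_frames), n_lags=cfg.n_lags, direction="anticausal")
    acc = np.zeros(target.n_bins)
    for seed in split_seeds:
        split = decoding_split(
            n_frames, vocal_mask, fixed_test, cfg.block_len_s, cfg.train_val_ratio, seed
        )
        rows_tr = base.rows_for_frames(split.train)
        rows_va = base.rows_for_frames(split.val)
        rows_te = base.rows_for_frames(split.test)
        scaler = fit_feature_scaler(base.X[rows_tr])
        X_tr = apply_scaler(scaler, base.X[rows_tr])
        X_va = apply_scaler(scaler, base.X[rows_va])
        X_te = apply_scaler(scaler, base.X[rows_te])
        for b in range(target.n_bins):
            y = target.values[base.frame_index, b]
            _, y_hat = _fit_predict(
                cfg, hyper, X_tr, y[rows_tr], X_va, y[rows_va], X_te, seed=seed + b
            )
            acc[b] += pearson_r(y[rows_te], y_hat)
    return acc / len(split_seeds)


@dataclass
class AblationResult:
    set_names: list[str]
    set_kinds: dict[str, str]
    baseline_r: np.ndarray  # per bin
    delta: dict[str, np.ndarray]  # per set: ablated minus baseline, per bin
    anova: pd.DataFrame | None = None
    posthoc: object | None = None
    significant: dict[str, bool] | None = None

    def long_table(self) -> pd.DataFrame:
        """Box-plot-ready long format: set, bin, r_baseline, r_ablated, delta."""
        rows = []
        for name in self.set_names:
            for b, d in enumerate(self.delta[name]):
                rows.append({
                    "set": name, "bin": b,
                    "r_baseline": self.baseline_r[b],
                    "r_ablated": self.baseline_r[b] + d,
                    "delta": d,
                })
        return pd.DataFrame(rows)


def ablate_and_decode(
    hfa: HfaMatrix,
    target: Spectrogram,
    sets: list[ElectrodeSet],
    cfg: DecoderConfig,
    fixed_test: tuple[int, int],
    vocal_mask: np.ndarray,
    seed: int = 0,
    n_splits: int = 3,
) -> AblationResult:
    """Refit per-bin linear decoders without each set and record delta r.

    The baseline is fitted once with all electrodes; every ablation reuses
    the identical split seeds.  Removing all electrodes is rejected.
    """
    if cfg.model_type != "linear":
        raise ValueError("ablation analysis is restricted to linear decoders")
    split_seeds = [int(s) for s in
                   np.random.SeedSequence((seed, 4)).generate_state(n_splits) % (2**31)]
    id_to_col = {e: i for i, e in enumerate(hfa.electrode_ids)}
    baseline_r = per_bin_decoder_r(
        hfa.values, target, cfg, fixed_test, vocal_mask, split_seeds
    )
    delta: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for s in sets:
        remove = {id_to_col[e] for e in s.members if e in id_to_col}
        keep = [i for i in range(hfa.n_electrodes) if i not in remove]
        if not keep:
            raise ValueError(f"ablating set {s.name} would remove every electrode")
        r = per_bin_decoder_r(
            hfa.values[:, keep], target, cfg, fixed_test, vocal_mask, split_seeds
        )
        delta[s.name] = r - baseline_r
        kinds[s.name] = s.kind
    result = AblationResult(
        set_names=[s.name for s in sets],
        set_kinds=kinds,
        baseline_r=baseline_r,
        delta=delta,
    )
    anova, posthoc, significant = ablation_anova(result)
    result.anova, result.posthoc, result.significant = anova, posthoc, significant
    return result


def ablation_anova(result: AblationResult, include_baseline: bool = True, alpha: float = 0.05):
    """Repeated-measures one-way ANOVA of delta r across sets (bins repeated).

    The baseline enters as a zero-delta level by default so post hoc
    Tukey-Kramer contrasts give a per-set significance vs baseline.
    Returns (anova table, Tukey result, {set: significant vs baseline}).
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(result.set_names)
    if include_baseline:
        names = ["baseline"] + names
    if len(names) < 2:
        raise ValueError("need at least 2 sets for the ANOVA")
    n_bins = result.baseline_r.size
    rows = []
    for name in names:
        d = np.zeros(n_bins) if name == "baseline" else result.delta[name]
        for b in range(n_bins):
            rows.append({"set": name, "bin": b, "delta": d[b]})
    df = pd.DataFrame(rows)
    anova = AnovaRM(df, depvar="delta", subject="bin", within=["set"]).fit().anova_table
    tukey = pairwise_tukeyhsd(df["delta"].to_numpy(), df["set"].to_numpy(), alpha=alpha)
    significant: dict[str, bool] = {}
    if include_baseline:
        summary = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
        for _, row in summary.iterrows():
            pair = {row["group1"], row["group2"]}
            if "baseline" in pair:
                other = (pair - {"baseline"}).pop()
                significant[other] = bool(row["reject"])
    return anova, tukey, significant


def classify_information(result: AblationResult) -> dict[str, str]:
    """Label each set's information as unique or redundant.

    Significant ablation impact -> unique; no significant impact (for
    electrodes with individually significant STRFs) -> redundant.
    Functional sets overlap by construction, so cross-set uniqueness
    comparisons among them are undetermined; the per-set label against
    baseline remains valid.
    """
    if result.significant is None:
        raise ValueError("run ablation_anova first")
    labels = {}
    for name in result.set_names:
        labels[name] = "unique" if result.significant.get(name, False) else "redundant"
    return labels
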