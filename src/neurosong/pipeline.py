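"""Configuration, orchestration and reporting for reproducible runs.

A run executes stages in order (simulate -> spectrogram -> preprocess ->
strf -> decode -> reconstruct -> identify -> components -> ablate ->
report), writing each stage's outputs under the run directory and a
manifest recording the package version, per-stage derived seeds, input
digests and produced files.  Per-stage seeds are derived from the master
seed by a stable hash of the stage name so stages are independently
reproducible.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    HfaMatrix,
    Spectrogram,
    load_npz,
    read_electrode_table,
    save_npz,
    write_electrode_table,
    write_json,
    read_json,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "spectrogram", "preprocess", "strf", "decode",
    "reconstruct", "identify", "components", "ablate", "report",
)


@dataclass
class RunConfig:
    """Desk-scale defaults; every stochastic stage gets a derived seed."""

    out_dir: str = "neurosong_run"
    audio_path: str | None = None
    recording_path: str | None = None
    electrode_table_path: str | None = None
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    # synthetic stimulus / cohort
    duration_s: float = 60.0
    tempo_bpm: float = 100.0
    vocal_interval: tuple[float, float] = (13.0, 40.0)
    n_bins: int = 16
    n_lags: int = 30
    n_per_archetype: int = 4
    n_noise: int = 8
    noise_sd: float = 1.0
    simulate_raw: bool = False
    # encoding
    n_boot: int = 30
    strf_learning_rate: float = 0.02
    strf_max_epochs: int = 400
    # decoding
    decoder_n_lags: int = 10
    n_models: int = 5
    n_tune_resamples: int = 3
    model_types: tuple[str, ...] = ("linear",)
    fixed_test_s: tuple[float, float] = (41.0, 51.0)
    block_len_s: float = 5.0
    # reconstruction
    gl_iterations: int = 50
    # identification
    n_segments: int = 6
    segment_len_s: float = 10.0
    excerpt_len_s: float = 2.0
    n_permutations: int = 1000
    # components / ablation
    k_probe: int = 6
    rhythm_threshold: float = 0.3
    ablation_n_splits: int = 2

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("stages", "vocal_interval", "fixed_test_s", "model_types"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        return zlib.crc32(f"{self.seed}:{stage}".encode()) % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunState:
    """In-memory artifacts handed between stages."""

    stimulus: object = None
    electrodes: list = field(default_factory=list)
    spectrogram: Spectrogram | None = None
    hfa: HfaMatrix | None = None
    electrode_table: pd.DataFrame | None = None
    strf_results: dict = field(default_factory=dict)
    z_maps: dict = field(default_factory=dict)
    decoded: dict = field(default_factory=dict)
    decoded_full: Spectrogram | None = None
    identification: dict = field(default_factory=dict)
    components: object = None
    assignments: pd.DataFrame | None = None
    ablation: object = None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    from . import synthetic, audio, preproc, features, encoding, decoding, identification, components, ablation

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}, "inputs": {}}
    for name, p in (("audio", config.audio_path), ("recording", config.recording_path),
                    ("electrode_table", config.electrode_table_path)):
        if p:
            manifest["inputs"][name] = {"path": p, "sha256": _digest(Path(p))}
    state = RunState()
    stages = list(config.stages)
    frame_rate = 100.0

    def require(artifact, stage: str, needed_by: str):
        if artifact is None:
            raise RuntimeError(
                f"stage '{needed_by}' needs output of '{stage}'; include it or provide the file"
            )

    for stage in stages:
        seed = config.stage_seed(stage)
        produced: list[str] = []
        if stage == "simulate":
            stim = synthetic.generate_stimulus(
                duration_s=config.duration_s, tempo_bpm=config.tempo_bpm,
                vocal_interval=config.vocal_interval, seed=seed,
                n_bins=config.n_bins,
            )
            counts = {a: config.n_per_archetype for a in ("onset", "sustained", "late_onset", "rhythmic")}
            electrodes = synthetic.generate_electrodes(
                counts, n_noise=config.n_noise, seed=seed + 1, noise_sd=config.noise_sd,
                n_bins=config.n_bins, n_lags=config.n_lags,
            )
            hfa = synthetic.simulate_hfa(stim, electrodes, seed=seed + 2)
            state.stimulus, state.electrodes, state.hfa = stim, electrodes, hfa
            state.spectrogram = stim.spectrogram
            state.electrode_table = synthetic.electrode_frame(electrodes)
            save_npz(out / "stimulus.npz",
                     spectrogram=stim.spectrogram.values,
                     center_frequencies=stim.spectrogram.center_frequencies,
                     vocal_mask=stim.vocal_mask, event_onsets_s=stim.event_onsets_s)
            save_npz(out / "hfa.npz", hfa=hfa.values, outlier_mask=hfa.outlier_mask)
            write_electrode_table(state.electrode_table, out / "electrodes.tsv")
            write_json({"seed": seed, "archetypes": {e.electrode_id: e.archetype for e in electrodes}},
                       out / "ground_truth.json")
            if config.simulate_raw:
                rec = synthetic.simulate_raw_ecog(hfa, seed=seed + 3)
                save_npz(out / "raw_ecog.npz", data=rec.data, fs=np.array(rec.fs),
                         splitter_group=rec.splitter_group, pad_s=np.array(rec.pad_s))
                produced.append("raw_ecog.npz")
            produced += ["stimulus.npz", "hfa.npz", "electrodes.tsv", "ground_truth.json"]
        elif stage == "spectrogram":
            if state.spectrogram is None:
                if not config.audio_path:
                    raise RuntimeError("stage 'spectrogram' needs an audio file or the simulate stage")
                wav = audio.read_wav(config.audio_path)
                state.spectrogram = audio.compute_auditory_spectrogram(wav, n_bins=config.n_bins)
            save_npz(out / "spectrogram.npz", values=state.spectrogram.values,
                     center_frequencies=state.spectrogram.center_frequencies)
            produced.append("spectrogram.npz")
        elif stage == "preprocess":
            if config.recording_path:
                arrays = load_npz(config.recording_path)
                table = read_electrode_table(config.electrode_table_path) if config.electrode_table_path else None
                from .containers import EcogRecording
                rec = EcogRecording(
                    data=arrays["data"], fs=float(arrays["fs"]),
                    electrode_ids=list(table["electrode_id"]) if table is not None
                    else [f"e{i:03d}" for i in range(arrays["data"].shape[1])],
                    splitter_group=arrays.get("splitter_group", np.zeros(arrays["data"].shape[1], int)),
                    pad_s=float(arrays.get("pad_s", 0.0)),
                )
                rec = preproc.remove_line_noise(rec)
                rec = preproc.highpass_drift(rec)
                state.hfa = preproc.extract_hfa(rec)
                if table is not None:
                    state.electrode_table = table
                save_npz(out / "hfa.npz", hfa=state.hfa.values, outlier_mask=state.hfa.outlier_mask)
                produced.append("hfa.npz")
            elif state.hfa is None:
                raise RuntimeError("stage 'preprocess' needs a recording file or the simulate stage")
        elif stage == "strf":
            require(state.hfa, "simulate/preprocess", stage)
            require(state.spectrogram, "spectrogram", stage)
            cfg = encoding.StrfConfig(
                learning_rate=config.strf_learning_rate, max_epochs=config.strf_max_epochs,
            )
            spec_log = audio.log_compress(state.spectrogram)
            vocal = getattr(state.stimulus, "vocal_mask", np.zeros(state.hfa.n_frames, bool))
            rows = []
            for j, eid in enumerate(state.hfa.electrode_ids):
                lm = features.build_lag_matrix(spec_log.values, state.hfa.values[:, j],
                                               n_lags=config.n_lags)
                lm, _ = features.drop_outlier_rows(lm, state.hfa.outlier_mask[:, j])
                ens, sig = encoding.bootstrap_strf(
                    lm, vocal, cfg, n_boot=config.n_boot, seed=seed + j,
                    n_frames=state.hfa.n_frames,
                )
                state.strf_results[eid] = (ens, sig)
                state.z_maps[eid] = ens.z_map
                rows.append({
                    "electrode_id": eid, "significant": sig.is_significant, "reason": sig.reason,
                    "r_mean": float(ens.r_samples.mean()), "ci_lo": ens.ci95_r[0],
                    "ci_hi": ens.ci95_r[1], "mean_r_squared": ens.mean_r_squared,
                })
            df = pd.DataFrame(rows)
            df.to_csv(out / "strf_summary.tsv", sep="\t", index=False)
            save_npz(out / "z_maps.npz", **{k: v for k, v in state.z_maps.items()})
            n_sig = int(df["significant"].sum())
            if state.electrode_table is not None:
                merged = state.electrode_table.merge(df, on="electrode_id")
                sig_df = merged[merged["significant"]]
                stats_rows = []
                for hemi in ("L", "R"):
                    k = int((sig_df["hemisphere"] == hemi).sum())
                    n = int((merged["hemisphere"] == hemi).sum())
                    stats_rows.append({"group": f"hemisphere_{hemi}", "significant": k, "total": n})
                pd.DataFrame(stats_rows).to_csv(out / "region_stats.tsv", sep="\t", index=False)
                produced.append("region_stats.tsv")
            write_json({"n_significant": n_sig}, out / "strf_counts.json")
            produced += ["strf_summary.tsv", "z_maps.npz", "strf_counts.json"]
        elif stage == "decode":
            require(state.hfa, "simulate/preprocess", stage)
            require(state.spectrogram, "spectrogram", stage)
            fixed = (int(config.fixed_test_s[0] * frame_rate), int(config.fixed_test_s[1] * frame_rate))
            vocal = getattr(state.stimulus, "vocal_mask", np.zeros(state.hfa.n_frames, bool))
            for model_type in config.model_types:
                cfg = decoding.DecoderConfig(
                    model_type=model_type, n_lags=config.decoder_n_lags,
                    n_models=config.n_models, block_len_s=config.block_len_s,
                    n_tune_resamples=config.n_tune_resamples,
                )
                dec = decoding.decode_spectrogram(
                    state.hfa, state.spectrogram, cfg, fixed, vocal_mask=vocal, seed=seed,
                )
                state.decoded[model_type] = dec
                save_npz(out / f"decoded_{model_type}.npz", predicted=dec.predicted,
                         effective_r2=dec.effective_r2, test_frames=dec.test_frames)
                write_json({"mean_effective_r2": float(dec.effective_r2.mean()),
                            "per_bin": dec.effective_r2.tolist(),
                            "best_n": dec.best_n.tolist()},
                           out / f"decode_metrics_{model_type}.json")
                produced += [f"decoded_{model_type}.npz", f"decode_metrics_{model_type}.json"]
        elif stage == "reconstruct":
            if not state.decoded:
                raise RuntimeError("stage 'reconstruct' needs the decode stage")
            for model_type, dec in state.decoded.items():
                spec = Spectrogram(
                    values=np.clip(dec.predicted, 0.0, None),
                    frame_rate=frame_rate,
                    center_frequencies=state.spectrogram.center_frequencies,
                    scale="magnitude",
                )
                spec = audio.square_magnitudes(spec)
                wav = audio.invert_spectrogram(spec, n_iter=config.gl_iterations, seed=seed)
                audio.write_wav(wav, out / f"reconstructed_{model_type}.wav")
                produced.append(f"reconstructed_{model_type}.wav")
        elif stage == "identify":
            require(state.hfa, "simulate/preprocess", stage)
            require(state.spectrogram, "spectrogram", stage)
            vocal = getattr(state.stimulus, "vocal_mask", np.zeros(state.hfa.n_frames, bool))
            cfg = decoding.DecoderConfig(
                model_type="linear", n_lags=config.decoder_n_lags,
                n_models=max(1, config.n_models // 2), block_len_s=config.block_len_s,
                n_tune_resamples=config.n_tune_resamples,
            )
            state.decoded_full = identification.decode_all_segments(
                state.hfa, state.spectrogram, cfg, vocal_mask=vocal,
                segment_len_s=config.segment_len_s, n_segments=config.n_segments, seed=seed,
            )
            corr = identification.excerpt_correlation_matrix(
                state.decoded_full, state.spectrogram, excerpt_len_s=config.excerpt_len_s,
            )
            ranks = identification.identification_ranks(corr)
            null = identification.permutation_null(corr, n_perm=config.n_permutations, seed=seed)
            state.identification = {
                "mean_normalized_rank": ranks.mean_normalized_rank,
                "n_top1": ranks.n_top1, "n_excerpts": ranks.n_excerpts,
                "null_ci95": list(null["null_ci95"]), "significant": null["significant"],
            }
            pd.DataFrame(corr.matrix).to_csv(out / "excerpt_correlations.tsv", sep="\t", index=False)
            save_npz(out / "identification_null.npz", null_samples=null["null_samples"])
            write_json(state.identification, out / "identification.json")
            produced += ["excerpt_correlations.tsv", "identification_null.npz", "identification.json"]
        elif stage == "components":
            if not state.z_maps:
                raise RuntimeError("stage 'components' needs the strf stage")
            sig_ids = [eid for eid, (ens, sig) in state.strf_results.items() if sig.is_significant]
            use_ids = sig_ids if len(sig_ids) >= config.k_probe else list(state.z_maps)
            maps = np.stack([state.z_maps[eid].ravel() for eid in use_ids])
            decomp = None
            k_probe = min(config.k_probe, len(use_ids))
            while k_probe >= 2:
                try:
                    decomp = components.ica_components(maps, k_probe=k_probe, seed=seed)
                    break
                except RuntimeError:
                    logger.warning("ICA with %d probe sources failed; retrying with fewer", k_probe)
                    k_probe -= 1
            if decomp is None:
                raise RuntimeError("ICA decomposition failed for every probe order >= 2")
            state.components = decomp
            flags = components.component_flags(decomp)
            max67 = np.array([components.max_modulation_6to7(state.z_maps[eid]) for eid in use_ids])
            rhythmic = components.rhythmic_assignment(max67, config.rhythm_threshold)
            assign = pd.DataFrame({"electrode_id": use_ids, "rhythmic": rhythmic, "max_6to7": max67})
            for i in range(decomp.k):
                assign[f"component_{i}"] = flags[:, i]
            state.assignments = assign
            if state.electrode_table is not None:
                merged = state.electrode_table.merge(assign, on="electrode_id", how="left")
                write_electrode_table(merged, out / "electrodes_with_components.tsv")
                produced.append("electrodes_with_components.tsv")
            save_npz(out / "ica.npz", components=decomp.components, mixing=decomp.mixing,
                     pvaf=decomp.pvaf)
            write_json({"k": decomp.k, "pvaf": decomp.pvaf.tolist(),
                        "total_pvaf_top3": float(np.sort(decomp.probe_pvaf)[::-1][:3].sum())},
                       out / "ica_summary.json")
            produced += ["ica.npz", "ica_summary.json"]
        elif stage == "ablate":
            require(state.hfa, "simulate/preprocess", stage)
            if state.electrode_table is None:
                raise RuntimeError("stage 'ablate' needs an electrode table")
            table = state.electrode_table.copy()
            if state.assignments is not None:
                table = table.merge(state.assignments, on="electrode_id", how="left")
            for comp in ("onset", "sustained", "late_onset", "rhythmic"):
                if comp not in table.columns and "archetype" in table.columns:
                    table[comp] = table["archetype"] == comp
            sets = ablation.define_sets(table)
            fixed = (int(config.fixed_test_s[0] * frame_rate), int(config.fixed_test_s[1] * frame_rate))
            vocal = getattr(state.stimulus, "vocal_mask", np.zeros(state.hfa.n_frames, bool))
            cfg = decoding.DecoderConfig(
                model_type="linear", n_lags=config.decoder_n_lags, block_len_s=config.block_len_s,
            )
            res = ablation.ablate_and_decode(
                state.hfa, state.spectrogram, sets, cfg, fixed, vocal,
                seed=seed, n_splits=config.ablation_n_splits,
            )
            state.ablation = res
            res.long_table().to_csv(out / "ablation.tsv", sep="\t", index=False)
            write_json({"labels": ablation.classify_information(res),
                        "significant": res.significant}, out / "ablation_summary.json")
            produced += ["ablation.tsv", "ablation_summary.json"]
        elif stage == "report":
            text = report(out)
            (out / "report.txt").write_text(text)
            produced.append("report.txt")
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest["stages"][stage] = {"seed": seed, "outputs": produced}
        logger.info("stage %s done (%d outputs)", stage, len(produced))

    digest_src = "".join(sorted(
        f"{s}:{o}" for s, info in manifest["stages"].items() for o in info["outputs"]
    ))
    manifest["digest"] = hashlib.sha256(
        (digest_src + str(config.seed)).encode()
    ).hexdigest()[:16]
    write_json(manifest, out / "manifest.json")
    return manifest


def report(run_dir: str | Path) -> str:
    """Human-readable summary of whatever stage outputs are present."""
    run_dir = Path(run_dir)
    lines = ["# neurosong run report", ""]
    found = False
    strf_path = run_dir / "strf_summary.tsv"
    if strf_path.exists():
        found = True
        df = pd.read_csv(strf_path, sep="\t")
        lines.append(f"## Encoding: {int(df['significant'].sum())}/{len(df)} significant electrodes")
        table_path = run_dir / "electrodes.tsv"
        if table_path.exists():
            table = read_electrode_table(table_path).merge(df, on="electrode_id")
            sig = table[table["significant"]]
            for (hemi, region), grp in sig.groupby(["hemisphere", "region"]):
                lines.append(f"  {hemi} {region}: {len(grp)}")
        lines.append("")
    for model_type in ("linear", "mlp"):
        p = run_dir / f"decode_metrics_{model_type}.json"
        if p.exists():
            found = True
            metrics = read_json(p)
            lines.append(f"## Decoding ({model_type}): mean effective r^2 = "
                         f"{metrics['mean_effective_r2']:.3f}")
    ident_path = run_dir / "identification.json"
    if ident_path.exists():
        found = True
        ident = read_json(ident_path)
        lines.append("")
        lines.append(
            f"## Identification: {ident['n_top1']}/{ident['n_excerpts']} top-1, mean normalized "
            f"rank {ident['mean_normalized_rank']:.3f} "
            f"(null CI95 {ident['null_ci95'][0]:.3f}-{ident['null_ci95'][1]:.3f}, "
            f"{'significant' if ident['significant'] else 'not significant'})"
        )
    ica_path = run_dir / "ica_summary.json"
    if ica_path.exists():
        found = True
        ica = read_json(ica_path)
        pv = ", ".join(f"{v:.1f}%" for v in ica["pvaf"])
        lines.append("")
        lines.append(f"## Components: k = {ica['k']} (pvaf {pv})")
    abl_path = run_dir / "ablation_summary.json"
    if abl_path.exists():
        found = True
        abl = read_json(abl_path)
        lines.append("")
        lines.append("## Ablation:")
        for name, label in abl["labels"].items():
            lines.append(f"  {name}: {label}")
    if not found:
        raise RuntimeError("no stage outputs found in run directory")
    return "\n".join(lines) + "\n"
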