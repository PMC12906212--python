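"""End-to-end experiment runners: noise robustness, reaction times,
difficulty-dependent pathway dominance, and hierarchical reconstruction.

Each runner is a pure function of (model, config, seeds): it writes tidy
CSV tables (plus lossless PNG panels for the reconstruction demo) into the
configured output directory together with a JSON manifest recording the
configuration, the seeds, and content hashes of the model weights, so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cortex_pc
from .decision import (ModelBundle, TrialProtocol, Winner, choice_accuracy,
                       difficulty_analysis, results_to_frame, rt_summary,
                       run_trials)
from .task import CueType, TrialSpec, make_test_set, render_cue, render_stimulus

log = logging.getLogger("shallowbrain")


def default_sigma_grid() -> list[float]:
    return [round(0.01 * i, 2) for i in range(21)]


@dataclass
class ExperimentConfig:
    model_variant: str = "ff"  # "ff" | "pc"
    sigma_grid: list[float] = field(default_factory=default_sigma_grid)
    n_repeats: int = 100
    n_test_pairs: int = 1000
    seed: int = 0
    protocol: TrialProtocol = field(default_factory=TrialProtocol)
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        proto = TrialProtocol(**raw.pop("protocol", {}))
        return cls(protocol=proto, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _hash_model(model: ModelBundle) -> str:
    h = hashlib.sha256()
    parts = []
    if model.variant == "ff":
        parts += [(f"cx_{k}", v) for k, v in model.ff_cortex.params.items()]
        parts += [(f"sc_{k}", v) for k, v in model.ff_subcortex.params.items()]
    else:
        parts += [("U1", model.pc_weights.U1), ("U2", model.pc_weights.U2),
                  ("clf_w", model.pc_classifier.w)]
        parts += [(k, v) for k, (v, _) in model.rnn.projections().items()]
    for k, v in sorted(parts, key=lambda kv: kv[0]):
        h.update(k.encode())
        h.update(np.ascontiguousarray(v).tobytes())
    return h.hexdigest()[:16]


def _write_manifest(outdir: Path, config: ExperimentConfig, model: ModelBundle,
                    extra: dict | None = None) -> None:
    manifest = dict(config=config.to_dict(), model_variant=model.variant,
                    weights_hash=_hash_model(model), **(extra or {}))
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_noise_robustness(model: ModelBundle, config: ExperimentConfig
                         ) -> pd.DataFrame:
    """Choice accuracy of the full model per noise level.

    For each sigma in the grid and each repeat, the same balanced test
    pairs (fixed by the config seed) are run as prosaccade and antisaccade
    trials in alternation and the fraction of correct saccades recorded.
    Writes per-(sigma, repeat) accuracies and a per-sigma mean +/- sd table.
    """
    outdir = Path(config.output_dir)
    test = make_test_set(config.n_test_pairs, seed=config.seed)
    # alternate cue conditions over the fixed pair list
    trials = [TrialSpec.make(CueType.PRO if i % 2 == 0 else CueType.ANTI, p)
              for i, p in enumerate(test.pairs)]
    rows = []
    for sigma in config.sigma_grid:
        for rep in range(config.n_repeats):
            rng = np.random.default_rng(
                (config.seed, int(round(sigma * 100)), rep))
            results, _ = run_trials(model, trials, sigma, config.protocol, rng)
            rows.append(dict(sigma=sigma, repeat=rep,
                             accuracy=choice_accuracy(results)))
        log.info("noise robustness sigma=%.2f done", sigma)
    table = pd.DataFrame(rows)
    summary = table.groupby("sigma")["accuracy"].agg(["mean", "std", "count"])
    _write_manifest(outdir, config, model, {"experiment": "noise_robustness"})
    table.to_csv(outdir / "noise_robustness.csv", index=False)
    summary.to_csv(outdir / "noise_robustness_summary.csv")
    return table


def run_rt_experiment(model: ModelBundle, config: ExperimentConfig,
                      sigma: float = 0.0) -> pd.DataFrame:
    """Reaction-time distributions per cue condition over a balanced test
    set; writes per-trial results and a per-cue (mean, sd, n) summary."""
    outdir = Path(config.output_dir)
    test = make_test_set(config.n_test_pairs, seed=config.seed)
    rng = np.random.default_rng((config.seed, 17))
    all_results = []
    for cue in CueType:
        trials = [TrialSpec.make(cue, p) for p in test.pairs]
        results, _ = run_trials(model, trials, sigma, config.protocol, rng)
        all_results += results
    frame = results_to_frame(all_results, model.variant, sigma)
    summary = rt_summary(all_results)
    _write_manifest(outdir, config, model, {"experiment": "rt", "sigma": sigma})
    frame.to_csv(outdir / "rt_trials.csv", index=False)
    summary.to_csv(outdir / "rt_summary.csv", index=False)
    return summary


def run_difficulty_experiment(model: ModelBundle, config: ExperimentConfig,
                              sigma: float = 0.0,
                              bins: np.ndarray | None = None) -> pd.DataFrame:
    """Winner counts, RTs, and the cortex/subcortex choice ratio per
    difficulty bin over prosaccade trials (subcortex is suppressed on
    antisaccade trials, so only PRO trials are informative)."""
    outdir = Path(config.output_dir)
    test = make_test_set(config.n_test_pairs, seed=config.seed)
    trials = [TrialSpec.make(CueType.PRO, p) for p in test.pairs]
    rng = np.random.default_rng((config.seed, 23))
    results, _ = run_trials(model, trials, sigma, config.protocol, rng)
    table = difficulty_analysis(results, bins)
    _write_manifest(outdir, config, model, {"experiment": "difficulty"})
    results_to_frame(results, model.variant, sigma).to_csv(
        outdir / "difficulty_trials.csv", index=False)
    table.to_csv(outdir / "difficulty_bins.csv", index=False)
    return table


def run_reconstruction_demo(model: ModelBundle, config: ExperimentConfig,
                            n_pairs: int = 4) -> pd.DataFrame:
    """Hierarchical reconstructions of sample screens from layers 1 and 2.

    Saves, for each sample screen, the input and both reconstructions as
    lossless PNGs plus a per-image squared-error table.
    """
    if model.variant != "pc":
        raise ValueError("reconstruction is defined for the PC variant only")
    import imageio.v3 as iio

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    test = make_test_set(max(n_pairs, 2), seed=config.seed)
    frames = [render_cue(CueType.PRO).grid, render_cue(CueType.ANTI).grid]
    names = ["cue_pro", "cue_anti"]
    for i, p in enumerate(test.pairs[:n_pairs]):
        frames.append(render_stimulus(p).grid)
        names.append(f"stim_{i}")
    x = np.stack(frames)
    st = cortex_pc.pc_infer(model.pc_weights, x, model.pc_hyper)
    rows = []
    for layer in (1, 2):
        recon = cortex_pc.reconstruct_from_layer(model.pc_weights, st, layer)
        for name, orig, rec_img in zip(names, x, recon):
            err = float(((orig - rec_img) ** 2).sum())
            rows.append(dict(frame=name, layer=layer, sq_error=err))
            _save_png(outdir / f"{name}_layer{layer}.png", rec_img)
    for name, orig in zip(names, x):
        _save_png(outdir / f"{name}_input.png", orig)
    table = pd.DataFrame(rows)
    _write_manifest(outdir, config, model, {"experiment": "reconstruction"})
    table.to_csv(outdir / "reconstruction_errors.csv", index=False)
    return table


def _save_png(path: Path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    lo, hi = img.min(), img.max()
    scaled = (255 * (img - lo) / (hi - lo + 1e-12)).astype(np.uint8)
    iio.imwrite(path, scaled)
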