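"""End-to-end orchestration: simulate -> preprocess -> split -> train ->
predict -> evaluate -> reconstruct.

Every stage writes its artifacts under one run directory and records a
fingerprint (hash of the effective config plus upstream fingerprints).  A
rerun skips stages whose outputs exist and whose fingerprints are unchanged,
so a pipeline is resumable per stage.  A stage failure aborts with the stage
name and its input fingerprint.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, evaluation, io, nn, segmentation, synthetic
from .config import RunConfig, dump_config
from .signal_processing import NormalizationParams

log = logging.getLogger("myogait")

STAGES = ("simulate", "preprocess", "split", "train", "predict",
          "evaluate", "reconstruct")


def _fingerprint(*parts) -> str:
    payload = json.dumps(parts, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class Runner:
    """Executes pipeline stages against one run directory."""

    def __init__(self, config: RunConfig, run_dir: Path):
        self.cfg = config
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.state_path = self.run_dir / ".stage_state.json"
        self.state = (
            json.loads(self.state_path.read_text()) if self.state_path.exists() else {}
        )
        self.muscles = config.muscle_list()
        self._setup_logging()

    def _setup_logging(self) -> None:
        if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
            fh = logging.FileHandler(self.run_dir / "pipeline.log")
            fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
            log.addHandler(fh)
        log.setLevel(logging.INFO)
        import scipy
        log.info("numpy %s, scipy %s, seed %d",
                 np.__version__, scipy.__version__, self.cfg.seed)
        dump_config(self.cfg, self.run_dir / "effective_config.yaml")

    def _save_state(self) -> None:
        self.state_path.write_text(json.dumps(self.state, indent=1))

    def _run_stage(self, name: str, fp: str, outputs: list[Path], fn) -> None:
        if self.state.get(name) == fp and all(p.exists() for p in outputs):
            log.info("stage %s up to date (fingerprint %s); skipped", name, fp)
            return
        log.info("stage %s starting (fingerprint %s)", name, fp)
        try:
            fn()
        except Exception as e:
            raise RuntimeError(
                f"pipeline stage {name!r} failed (input fingerprint {fp}): {e}"
            ) from e
        self.state[name] = fp
        self._save_state()
        log.info("stage %s done", name)

    # stages -----------------------------------------------------------------
    def simulate(self) -> Path:
        out = self.run_dir / "raw"
        fp = _fingerprint("simulate", self.cfg.seed,
                          self.cfg.synthetic.model_dump())
        self._run_stage("simulate", fp, [out / "manifest.json"], lambda: io.write_study(
            synthetic.generate_study(seed=self.cfg.seed,
                                     config=self.cfg.synthetic.to_config()),
            out,
        ))
        return out

    def preprocess(self) -> Path:
        out = self.run_dir / "cycles.h5"
        fp = _fingerprint("preprocess", self.state.get("simulate"),
                          self.cfg.signal.model_dump(), self.muscles)

        def _do() -> None:
            trials, muscles = io.read_study(self.run_dir / "raw")
            muscles = [m for m in muscles if m in self.muscles]
            samples = datasets.build_samples(trials, muscles,
                                             self.cfg.signal.to_config())
            io.save_cycles(out, samples, muscles)

        self._run_stage("preprocess", fp, [out], _do)
        return out

    def split(self) -> Path:
        out = self.run_dir / "split.csv"
        fp = _fingerprint("split", self.state.get("preprocess"),
                          self.cfg.split.model_dump(), self.cfg.seed)

        def _do() -> None:
            samples, _ = io.load_cycles(self.run_dir / "cycles.h5")
            split = self._make_split(samples)
            io.write_split_manifest(out, split)

        self._run_stage("split", fp, [out], _do)
        return out

    def _make_split(self, samples) -> datasets.DatasetSplit:
        sb = self.cfg.split
        unseen_id = sb.unseen_subject
        if unseen_id == "random":
            subjects = sorted({s.subject_id for s in samples})
            unseen_id = subjects[
                np.random.default_rng(self.cfg.seed).integers(len(subjects))
            ]
        remaining, unseen = datasets.holdout_subject(samples, unseen_id)
        split = datasets.split_dataset(remaining, tuple(sb.ratios),
                                       seed=self.cfg.seed, by=sb.by)
        split.unseen_subject = unseen
        return split

    def _load_split(self) -> datasets.DatasetSplit:
        samples, _ = io.load_cycles(self.run_dir / "cycles.h5")
        manifest = pd.read_csv(self.run_dir / "split.csv")
        groups = {
            (r.subject_id, r.trial_id, r.stride_index): r.group
            for r in manifest.itertuples()
        }
        split = datasets.DatasetSplit([], [], [], [], seed=self.cfg.seed)
        bucket = {"train": split.train, "validation": split.validation,
                  "test": split.test, "unseen_subject": split.unseen_subject}
        for s in samples:
            g = groups.get((s.subject_id, s.trial_id, s.stride_index))
            if g is not None:
                bucket[g].append(s)
        return split

    def _model_path(self, arch: str, muscle: str) -> Path:
        return self.run_dir / "models" / f"{arch}_{muscle}"

    def train(self, architectures=None, muscles=None) -> None:
        archs = architectures or self.cfg.model.architectures
        muscles = muscles or self.muscles
        fp = _fingerprint("train", self.state.get("split"),
                          self.cfg.model.model_dump(), archs, muscles, self.cfg.seed)
        outputs = [self._model_path(a, m).with_suffix(".npz")
                   for a in archs for m in muscles]

        def _do() -> None:
            (self.run_dir / "models").mkdir(exist_ok=True)
            split = self._load_split()
            mb = self.cfg.model
            for arch in archs:
                shape = (
                    (segmentation.N_PHASE_POINTS * datasets.N_FEATURES,)
                    if arch == "fnn"
                    else (segmentation.N_PHASE_POINTS, datasets.N_FEATURES)
                )
                for mi, muscle in enumerate(muscles):
                    cfg = nn.ModelConfig(
                        architecture=arch,
                        hidden_layers=mb.hidden_layers,
                        hidden_units=mb.hidden_units,
                        dropout_rate=mb.dropout_rate,
                        learning_rate=mb.learning_rate,
                        batch_size=mb.batch_size,
                        max_epochs=mb.max_epochs,
                        early_stop_patience=mb.early_stop_patience,
                        seed=self.cfg.seed + 1000 * mi,
                    )
                    est = nn.build_estimator(cfg, shape)
                    nn.train(est, split, muscle)
                    est.save(self._model_path(arch, muscle))
                    log.info("trained %s/%s: best val MSE %.5f (%d epochs)",
                             arch, muscle, min(est.history["val_loss"]),
                             len(est.history["val_loss"]))

        self._run_stage("train", fp, outputs, _do)

    def predict(self) -> Path:
        out = self.run_dir / "predictions.npz"
        fp = _fingerprint("predict", self.state.get("train"))

        def _do() -> None:
            split = self._load_split()
            arrays: dict = {}
            for arch in self.cfg.model.architectures:
                flat = arch == "fnn"
                for muscle in self.muscles:
                    est = nn.load_estimator(self._model_path(arch, muscle))
                    for group in ("test", "unseen_subject"):
                        ss = getattr(split, group)
                        if not ss:
                            continue
                        x = datasets.stack_features(ss, flatten=flat)
                        arrays[f"{arch}/{muscle}/{group}/predicted"] = est.predict(x)
                        arrays[f"{arch}/{muscle}/{group}/actual"] = (
                            datasets.stack_targets(ss, muscle)
                        )
            np.savez(out, **arrays)

        self._run_stage("predict", fp, [out], _do)
        return out

    def evaluate(self) -> Path:
        out = self.run_dir / "report.csv"
        fp = _fingerprint("evaluate", self.state.get("predict"))

        def _do() -> None:
            rows = []
            with np.load(self.run_dir / "predictions.npz") as data:
                keys = {tuple(k.split("/")[:3]) for k in data.files}
                for arch, muscle, group in sorted(keys):
                    row = evaluation.evaluate_group(
                        data[f"{arch}/{muscle}/{group}/actual"],
                        data[f"{arch}/{muscle}/{group}/predicted"],
                        muscle, group,
                    )
                    row["architecture"] = arch
                    rows.append(row)
            evaluation.write_report(rows, out, self.run_dir / "report.json")

        self._run_stage("evaluate", fp, [out], _do)
        return out

    def reconstruct(self) -> Path:
        """Stitch the unseen subject's predicted envelopes back into time."""
        out = self.run_dir / "reconstructed"
        fp = _fingerprint("reconstruct", self.state.get("predict"))

        def _do() -> None:
            out.mkdir(exist_ok=True)
            split = self._load_split()
            ss = split.unseen_subject or split.test
            by_trial: dict = {}
            for s in ss:
                by_trial.setdefault((s.subject_id, s.trial_id), []).append(s)
            (sid, tid), group = sorted(by_trial.items())[0]
            group.sort(key=lambda s: s.stride_index)
            # contiguous strides only, for a gap-free reconstruction
            contiguous = [group[0]]
            for s in group[1:]:
                if s.stride_index == contiguous[-1].stride_index + 1:
                    contiguous.append(s)
                else:
                    break
            strikes = np.array([s.start_s for s in contiguous]
                               + [contiguous[-1].end_s])
            arch = self.cfg.model.architectures[-1]
            flat = arch == "fnn"
            fs_out = 100.0
            cols = {}
            for muscle in self.muscles:
                est = nn.load_estimator(self._model_path(arch, muscle))
                x = datasets.stack_features(contiguous, flatten=flat)
                preds = est.predict(x)
                cycles = [
                    segmentation.NormalizedCycle(
                        p, s.target_params[muscle], s.start_s, s.end_s, muscle
                    )
                    for p, s in zip(preds, contiguous)
                ]
                sig = segmentation.reconstruct_time_domain(cycles, strikes, fs_out)
                cols[f"emg_{muscle}"] = sig.samples
            t = strikes[0] + np.arange(len(next(iter(cols.values())))) / fs_out
            df = pd.DataFrame({"time_s": t, **cols})
            df.to_csv(out / f"{sid}_{tid}_{arch}_predicted.csv", index=False,
                      float_format="%.6g")

        self._run_stage("reconstruct", fp, [out], _do)
        return out


def run_pipeline(config: RunConfig, run_dir: Path) -> Path:
    """Run every stage in order; returns the run directory."""
    runner = Runner(config, run_dir)
    runner.simulate()
    runner.preprocess()
    runner.split()
    runner.train()
    runner.predict()
    runner.evaluate()
    runner.reconstruct()
    return runner.run_dir
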