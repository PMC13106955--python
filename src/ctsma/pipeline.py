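"""End-to-end orchestration: phantom cohort -> registration -> synthesis ->
distillation -> aggregation -> evaluation.

A run executes eleven stages in dependency order, each writing its artifacts
under the output directory and recording content hashes in ``manifest.json``;
re-running with ``resume=True`` skips stages whose outputs are present with
matching hashes.  All randomness derives from the single run seed.  Scale
presets ("toy", "small", "full") pin cohort size, patch counts and network
budgets; "toy" completes on one CPU in a few minutes.

At deployment the trained student and aggregator consume CT alone:
:func:`ct_only_inference` runs the full patient-level readout with no MR
artifact present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import distill as dst
from . import evaluation as ev
from . import phantoms as ph
from . import registration as reg
from . import synthesis as syn
from .core import RigidTransform, Volume3D, load_volume, save_volume

__all__ = [
    "RunConfig",
    "RunManifest",
    "validate_config",
    "run_pipeline",
    "ct_only_inference",
    "STAGES",
]

STAGES = (
    "cohort",
    "coarse_registration",
    "synthesis",
    "refined_registration",
    "patch_pairs",
    "morphometry_truth",
    "teacher",
    "student",
    "tokens",
    "aggregator",
    "evaluation",
)

_SCALE_PRESETS = {
    # cohort            patches  synthesis            distillation          aggregation
    "toy": dict(n_subjects=12, n_train_subjects=8, patches_per_subject=60,
                synth_steps=150, synth_width=6, synth_subjects=2,
                teacher_width=4, student_width=4, teacher_epochs=12, student_epochs=10,
                distill_lr=3e-3, distill_dropout=0.2, subregions=24, agg_epochs=150),
    "small": dict(n_subjects=24, n_train_subjects=18, patches_per_subject=90,
                  synth_steps=300, synth_width=8, synth_subjects=3,
                  teacher_width=6, student_width=4, teacher_epochs=8, student_epochs=5,
                  distill_lr=3e-3, distill_dropout=0.2, subregions=40, agg_epochs=150),
    "full": dict(n_subjects=80, n_train_subjects=64, patches_per_subject=100,
                 synth_steps=5000, synth_width=16, synth_subjects=10,
                 teacher_width=12, student_width=8, teacher_epochs=50, student_epochs=50,
                 distill_lr=3e-4, distill_dropout=0.5, subregions=100, agg_epochs=400),
}


@dataclass
class RunConfig:
    out_dir: str = "runs/ctsma"
    seed: int = 0
    scale: str = "toy"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    synthesis: dict = field(default_factory=dict)  # SynthConfig overrides
    distill: dict = field(default_factory=dict)  # DistillConfig overrides
    aggregator: dict = field(default_factory=dict)  # AggregatorConfig overrides
    use_synthesis: bool = True  # refine on sCT (the full pipeline) vs crMR

    def __post_init__(self) -> None:
        if self.scale not in _SCALE_PRESETS:
            raise ValueError(f"unknown scale preset {self.scale!r}")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        lam = self.synthesis.get("weights")
        if isinstance(lam, dict) and (lam.get("lambda_cyc", 0) < 0 or lam.get("lambda_mi", 0) < 0):
            raise ValueError("synthesis loss weights must be non-negative")

    @property
    def preset(self) -> dict:
        return _SCALE_PRESETS[self.scale]


def validate_config(path_or_dict) -> RunConfig:
    """Load + schema-check a YAML run configuration; unknown keys rejected."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        warnings.warn("no seed in config; defaulting to 0")
    return RunConfig(**raw)


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)  # name -> {files: {path: sha}, time_s}

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh, indent=2)

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["config"], d["stages"])


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# --- model persistence ------------------------------------------------------

def save_model_arrays(path: Path, arrays: list[np.ndarray], meta: dict) -> None:
    np.savez(path, **{f"a{i}": a for i, a in enumerate(arrays)})
    wh = hashlib.sha256(b"".join(np.ascontiguousarray(a).tobytes() for a in arrays)).hexdigest()
    with open(str(path) + ".json", "w") as fh:
        json.dump({**meta, "weights_sha256": wh, "n_arrays": len(arrays)}, fh, indent=2)


def load_model_arrays(path: Path) -> tuple[list[np.ndarray], dict]:
    with np.load(str(path)) as z:
        arrays = [z[f"a{i}"] for i in range(len(z.files))]
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return arrays, meta


def save_regression_model(model: dst.RegressionModel, path: Path) -> None:
    meta = {"role": model.role, "config": dataclasses.asdict(model.config),
            "std_mean": model.standardizer.mean.tolist(),
            "std_sd": model.standardizer.sd.tolist()}
    save_model_arrays(path, model.net.state_dict(), meta)


def load_regression_model(path: Path) -> dst.RegressionModel:
    arrays, meta = load_model_arrays(path)
    cfg = dst.DistillConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in meta["config"].items()})
    strides = (2, 2, 2) if meta["role"] == "teacher" else (1, 2, 2)
    net = dst.Regressor3D(cfg.width, strides, np.random.default_rng(0),
                          dropout=cfg.dropout, anisotropic_first=meta["role"] == "teacher")
    net.load_state_dict(arrays)
    std = dst._Standardizer(np.asarray(meta["std_mean"]), np.asarray(meta["std_sd"]))
    return dst.RegressionModel(net, std, meta["role"], cfg)


def save_aggregator(model, path: Path) -> None:
    meta = {"config": dataclasses.asdict(model.config),
            "architecture": type(model).__name__,
            "param_shift": model.param_shift.tolist(),
            "param_scale": model.param_scale.tolist(),
            "score_mean": model.score_mean, "score_sd": model.score_sd}
    save_model_arrays(path, model.state_dict(), meta)


def load_aggregator(path: Path):
    arrays, meta = load_model_arrays(path)
    cfg = agg.AggregatorConfig(**meta["config"])
    cls = agg.AggregatorModel if meta["architecture"] == "AggregatorModel" else agg.MeanMLPBaseline
    model = cls(cfg, np.random.default_rng(0))
    model.load_state_dict(arrays)
    model.param_shift = np.asarray(meta["param_shift"])
    model.param_scale = np.asarray(meta["param_scale"])
    model.score_mean, model.score_sd = meta["score_mean"], meta["score_sd"]
    return model


def save_synth_model(model: syn.SynthModel, path: Path) -> None:
    arrays, sizes = [], []
    for part in (model.G1, model.G2, model.D1, model.D2):
        st = part.state_dict()
        sizes.append(len(st))
        arrays += st
    meta = {"config": {**dataclasses.asdict(model.config),
                       "weights": dataclasses.asdict(model.config.weights)},
            "part_sizes": sizes}
    save_model_arrays(path, arrays, meta)


def load_synth_model(path: Path) -> syn.SynthModel:
    arrays, meta = load_model_arrays(path)
    cdict = dict(meta["config"])
    cdict["weights"] = syn.SynthLossWeights(**cdict["weights"])
    cfg = syn.SynthConfig(**cdict)
    rng = np.random.default_rng(0)
    model = syn.SynthModel(
        G1=syn.Generator(cfg.k_slices, cfg.width, cfg.n_res_blocks, rng),
        G2=syn.Generator(cfg.k_slices, cfg.width, cfg.n_res_blocks, rng),
        D1=syn.Discriminator(cfg.disc_width, rng),
        D2=syn.Discriminator(cfg.disc_width, rng), config=cfg)
    i = 0
    for part, nsz in zip((model.G1, model.G2, model.D1, model.D2), meta["part_sizes"]):
        part.load_state_dict(arrays[i:i + nsz])
        i += nsz
    return model


# --- the run ----------------------------------------------------------------

class _Run:
    """Stage executor holding the shared state of one pipeline run."""

    def __init__(self, config: RunConfig, resume: bool):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.preset = config.preset
        mpath = self.out / "manifest.json"
        if resume and mpath.exists():
            self.manifest = RunManifest.load(mpath)
        else:
            self.manifest = RunManifest(dataclasses.asdict(config))
        self.subjects: list[ph.CohortSubject] | None = None
        self.pairs: list[dst.PatchPair] | None = None

    # -- helpers
    def _done(self, stage: str, files: list[Path]) -> None:
        self.manifest.stages[stage] = {
            "files": {str(f.relative_to(self.out)): _sha(f) for f in files},
            "time_s": round(time.time() - self._t0, 2)}
        self.manifest.save(self.out / "manifest.json")

    def _skippable(self, stage: str) -> bool:
        rec = self.manifest.stages.get(stage)
        if not rec:
            return False
        for relpath, sha in rec["files"].items():
            f = self.out / relpath
            if not f.exists() or _sha(f) != sha:
                return False
        return True

    def _train_ids(self) -> set[str]:
        n_train = self.preset["n_train_subjects"]
        return {f"S{i:03d}" for i in range(n_train)}

    def subject_dir(self, sid: str) -> Path:
        d = self.out / "subjects" / sid
        d.mkdir(parents=True, exist_ok=True)
        return d

    # -- stages
    def stage_cohort(self):
        spec = ph.CohortSpec(n_subjects=self.preset["n_subjects"],
                             seed=self.cfg.seed, **self.cfg.cohort)
        self.subjects = ph.generate_cohort(spec)
        files = []
        rows = []
        for s in self.subjects:
            d = self.subject_dir(s.subject_id)
            save_volume(s.ct, d / "ct.nii.gz")
            save_volume(s.mr_misaligned, d / "mr.nii.gz")
            save_volume(s.phantom.microstructure, d / "micro.nii.gz")
            save_volume(s.phantom.bone_labels, d / "labels.nii.gz")
            s.landmarks.to_csv(d / "landmarks.csv", index=False)
            files += [d / "ct.nii.gz", d / "mr.nii.gz", d / "landmarks.csv"]
            rows.append({"subject_id": s.subject_id, "class": s.class_label,
                         "score": s.score, "split": "train" if s.subject_id
                         in self._train_ids() else "test"})
        pd.DataFrame(rows).to_csv(self.out / "cohort.csv", index=False)
        self._done("cohort", files + [self.out / "cohort.csv"])

    def stage_coarse_registration(self):
        files = []
        for s in self.subjects:
            d = self.subject_dir(s.subject_id)
            res = reg.register_rigid(s.mr_misaligned, s.ct)
            res.transform.save_json(d / "coarse_tf.json")
            cr = reg.resample_to_grid(s.mr_misaligned, s.ct, motion=res.transform)
            save_volume(cr, d / "crmr.nii.gz")
            files += [d / "coarse_tf.json", d / "crmr.nii.gz"]
        self._done("coarse_registration", files)

    def stage_synthesis(self):
        files = []
        train = [s for s in self.subjects[: self.preset["synth_subjects"]]]
        mr_vols = [load_volume(self.subject_dir(s.subject_id) / "crmr.nii.gz") for s in train]
        ct_vols = [s.ct for s in train]
        cfg = syn.SynthConfig(max_steps=self.preset["synth_steps"],
                              width=self.preset["synth_width"], lr=1e-3,
                              seed=self.cfg.seed, **self.cfg.synthesis)
        model, history = syn.train_spsnet(mr_vols, ct_vols, cfg)
        save_synth_model(model, self.out / "spsnet.npz")
        with open(self.out / "spsnet_history.json", "w") as fh:
            json.dump(history, fh)
        for s in self.subjects:
            d = self.subject_dir(s.subject_id)
            sct = syn.synthesize(model, load_volume(d / "crmr.nii.gz"))
            save_volume(sct, d / "sct.nii.gz")
            files.append(d / "sct.nii.gz")
        self._done("synthesis", files + [self.out / "spsnet.npz",
                                         self.out / "spsnet_history.json"])

    def stage_refined_registration(self):
        files, rows = [], []
        src_name = "sct.nii.gz" if self.cfg.use_synthesis else "crmr.nii.gz"
        for s in self.subjects:
            d = self.subject_dir(s.subject_id)
            moving = load_volume(d / src_name)
            lab_ct = reg.resample_to_grid(s.phantom.bone_labels, s.ct,
                                          interpolation="nearest")
            mf, mt = lab_ct.data == 1, lab_ct.data == 2
            rf, rt = reg.register_bonewise(moving, s.ct, mf, mt)
            rf.transform.save_json(d / "refine_femur.json")
            rt.transform.save_json(d / "refine_tibia.json")
            rr = reg.compose_bonewise(moving, rf.transform, rt.transform, mf, mt,
                                      fixed=s.ct)
            save_volume(rr, d / "rrmr.nii.gz")
            coarse = RigidTransform.load_json(d / "coarse_tf.json")
            for bone, r in (("femur", rf), ("tibia", rt)):
                lmb = s.landmarks[s.landmarks.bone == bone]
                fixed_pts = lmb[["x_mm", "y_mm", "z_mm"]].to_numpy()
                moved_pts = lmb[["xt_mm", "yt_mm", "zt_mm"]].to_numpy()
                total = r.transform.compose(coarse)
                tre_c = reg.target_registration_error(fixed_pts, moved_pts, coarse)
                tre_r = reg.target_registration_error(fixed_pts, moved_pts, total)
                rows.append({"subject_id": s.subject_id, "bone": bone,
                             "tre_coarse_mm": tre_c["mean"], "tre_refined_mm": tre_r["mean"]})
            files += [d / "refine_femur.json", d / "refine_tibia.json", d / "rrmr.nii.gz"]
        pd.DataFrame(rows).to_csv(self.out / "tre.csv", index=False)
        self._done("refined_registration", files + [self.out / "tre.csv"])

    def _aligned_mr(self, s: ph.CohortSubject) -> Volume3D:
        """Per-bone refined alignment applied to the misaligned MR, composited
        on the MR-resolution grid by nearest compartment."""
        d = self.subject_dir(s.subject_id)
        coarse = RigidTransform.load_json(d / "coarse_tf.json")
        rf = RigidTransform.load_json(d / "refine_femur.json").compose(coarse)
        rt = RigidTransform.load_json(d / "refine_tibia.json").compose(coarse)
        from scipy import ndimage as ndi

        labels = s.phantom.bone_labels.data
        d1 = ndi.distance_transform_edt(labels != 1, sampling=s.phantom.bone_labels.spacing)
        d2 = ndi.distance_transform_edt(labels != 2, sampling=s.phantom.bone_labels.spacing)
        femur_region = d1 <= d2
        vf = reg.resample_to_grid(s.mr_misaligned, s.phantom.intensity, motion=rf)
        vt = reg.resample_to_grid(s.mr_misaligned, s.phantom.intensity, motion=rt)
        return s.phantom.intensity.copy_with(np.where(femur_region, vf.data, vt.data))

    def stage_patch_pairs(self):
        self.pairs = []
        for s in self.subjects:
            mr_aligned = self._aligned_mr(s)
            mask = Volume3D((s.phantom.bone_labels.data > 0).astype(np.uint8),
                            s.phantom.bone_labels.spacing, s.phantom.bone_labels.origin)
            sub_seed = self.cfg.seed * 100003 + int(s.subject_id[1:])
            self.pairs += dst.sample_patch_pairs(
                mr_aligned, s.ct, mask, self.preset["patches_per_subject"],
                seed=sub_seed % (2**31), subject_id=s.subject_id)
        rows = [{"subject_id": p.subject_id, "cx": p.center[0], "cy": p.center[1],
                 "cz": p.center[2]} for p in self.pairs]
        pd.DataFrame(rows).to_csv(self.out / "patches.csv", index=False)
        self._done("patch_pairs", [self.out / "patches.csv"])

    def stage_morphometry_truth(self):
        by_subject = {s.subject_id: s for s in self.subjects}
        kept = []
        for p in self.pairs:
            s = by_subject[p.subject_id]
            tb = dst.extract_patch(s.phantom.microstructure, p.center, dst.MR_PATCH)
            if tb is None:
                continue
            try:
                p.truth = dst.compute_params(tb.astype(np.uint8),
                                             s.phantom.microstructure.spacing)
            except dst.DegeneratePatchError:
                continue
            kept.append(p)
        self.pairs = kept
        rows = [{"subject_id": p.subject_id, "cx": p.center[0], "cy": p.center[1],
                 "cz": p.center[2], **dict(zip(("bvtv", "tbth_mm", "tbsp_mm",
                                                "tbn_per_mm"), p.truth.as_array()))}
                for p in self.pairs]
        pd.DataFrame(rows).to_csv(self.out / "patch_truth.csv", index=False)
        self._done("morphometry_truth", [self.out / "patch_truth.csv"])

    def _distill_cfg(self, width_key: str, epochs_key: str, seed_off: int) -> dst.DistillConfig:
        base = dict(width=self.preset[width_key], epochs=self.preset[epochs_key],
                    lr=self.preset["distill_lr"], dropout=self.preset["distill_dropout"],
                    seed=self.cfg.seed + seed_off)
        base.update(self.cfg.distill)
        return dst.DistillConfig(**base)

    def stage_teacher(self):
        tr = [p for p in self.pairs if p.subject_id in self._train_ids()]
        cfg = self._distill_cfg("teacher_width", "teacher_epochs", 1)
        teacher, hist = dst.train_teacher(np.array([p.mr_patch for p in tr]),
                                          [p.truth for p in tr], cfg)
        save_regression_model(teacher, self.out / "teacher.npz")
        with open(self.out / "teacher_history.json", "w") as fh:
            json.dump(hist, fh)
        self._done("teacher", [self.out / "teacher.npz", self.out / "teacher_history.json"])

    def stage_student(self):
        tr = [p for p in self.pairs if p.subject_id in self._train_ids()]
        teacher = load_regression_model(self.out / "teacher.npz")
        cfg = self._distill_cfg("student_width", "student_epochs", 2)
        student, hist = dst.train_student(tr, teacher, dst.DistillWeights(), cfg)
        save_regression_model(student, self.out / "student.npz")
        with open(self.out / "student_history.json", "w") as fh:
            json.dump(hist, fh)
        self._done("student", [self.out / "student.npz", self.out / "student_history.json"])

    def stage_tokens(self):
        student = load_regression_model(self.out / "student.npz")
        rows = []
        for s in self.subjects:
            mask_mr = Volume3D((s.phantom.bone_labels.data > 0).astype(np.uint8),
                               s.phantom.bone_labels.spacing, s.phantom.bone_labels.origin)
            centers = agg.partition_subregions(mask_mr, self.preset["subregions"])
            patches, kept = [], []
            for c in centers:
                patch = dst.extract_patch(s.ct, c, dst.CT_PATCH)
                if patch is not None:
                    patches.append(patch)
                    kept.append(c)
            preds = student.predict(np.array(patches))
            for c, y in zip(kept, preds):
                rows.append({"subject_id": s.subject_id, "cx": c[0], "cy": c[1],
                             "cz": c[2], "bvtv": y[0], "tbth_mm": y[1],
                             "tbsp_mm": y[2], "tbn_per_mm": y[3]})
        pd.DataFrame(rows).to_csv(self.out / "tokens.csv", index=False)
        self._done("tokens", [self.out / "tokens.csv"])

    def _records(self) -> list[agg.PatientRecord]:
        tokens = pd.read_csv(self.out / "tokens.csv")
        cohort = pd.read_csv(self.out / "cohort.csv").set_index("subject_id")
        records = []
        for sid, g in tokens.groupby("subject_id"):
            s = next(x for x in self.subjects if x.subject_id == sid)
            lo = np.asarray(s.ct.origin)
            hi = lo + np.asarray(s.ct.extent_mm)
            records.append(agg.PatientRecord(
                sid, g[["bvtv", "tbth_mm", "tbsp_mm", "tbn_per_mm"]].to_numpy(),
                g[["cx", "cy", "cz"]].to_numpy(),
                int(cohort.loc[sid, "class"]), float(cohort.loc[sid, "score"]),
                bounds=(lo, hi)))
        return records

    def stage_aggregator(self):
        records = self._records()
        train = [r for r in records if r.subject_id in self._train_ids()]
        cfg = agg.AggregatorConfig(epochs=self.preset["agg_epochs"],
                                   seed=self.cfg.seed + 3, **self.cfg.aggregator)
        model, hist = agg.train_aggregator(train, cfg)
        save_aggregator(model, self.out / "aggregator.npz")
        with open(self.out / "aggregator_history.json", "w") as fh:
            json.dump(hist, fh)
        self._done("aggregator", [self.out / "aggregator.npz",
                                  self.out / "aggregator_history.json"])

    def stage_evaluation(self):
        by_subject = {s.subject_id: s for s in self.subjects}
        test_ids = {s.subject_id for s in self.subjects} - self._train_ids()
        student = load_regression_model(self.out / "student.npz")
        te = [p for p in self.pairs if p.subject_id in test_ids]
        pred = student.predict(np.array([p.ct_patch for p in te]))
        truth = np.array([p.truth.as_array() for p in te])
        agreement = ev.agreement_report(pred, truth)

        model = load_aggregator(self.out / "aggregator.npz")
        records = [r for r in self._records() if r.subject_id in test_ids]
        preds = agg.predict_cohort(model, records)
        labels_bin = np.array([int(by_subject[r.subject_id].class_label > 0)
                               for r in records])
        pred_bin = (preds["p_oa"].to_numpy() > 0.5).astype(int)
        diag = ev.classification_report(labels_bin, pred_bin,
                                        preds["p_oa"].to_numpy(), seed=self.cfg.seed)
        score_rep = ev.score_regression_report(
            [by_subject[r.subject_id].score for r in records],
            preds["score_hat"].to_numpy())
        tre = pd.read_csv(self.out / "tre.csv")
        report = {
            "tre_coarse_mm": float(tre["tre_coarse_mm"].mean()),
            "tre_refined_mm": float(tre["tre_refined_mm"].mean()),
            "icc": agreement.per_parameter,
            "icc_overall": agreement.overall,
            "icc_form": agreement.icc_form,
            "n_test_patches": agreement.n_pairs,
            "classification": {"precision": diag.precision, "recall": diag.recall,
                               "f1": diag.f1, "auc": diag.auc,
                               "auc_ci95": list(diag.auc_ci95)},
            "score": score_rep,
        }
        with open(self.out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        preds.to_csv(self.out / "predictions.csv", index=False)
        self._done("evaluation", [self.out / "report.json", self.out / "predictions.csv"])

    def execute(self) -> RunManifest:
        for stage in STAGES:
            if not self.cfg.stages.get(stage, True):
                continue
            if stage == "synthesis" and not self.cfg.use_synthesis:
                continue
            self._t0 = time.time()
            if self._skippable(stage):
                self._restore_state(stage)
                continue
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                self.manifest.stages[stage] = {"status": "failed", "error": str(exc)}
                self.manifest.save(self.out / "manifest.json")
                raise PipelineStageError(stage, str(exc)) from exc
        return self.manifest

    def _rebuild_pairs(self, df: pd.DataFrame, with_truth: bool) -> list[dst.PatchPair]:
        by_subject = {s.subject_id: s for s in self.subjects}
        pairs = []
        for _, row in df.iterrows():
            s = by_subject[row.subject_id]
            c = np.array([row.cx, row.cy, row.cz])
            ct_patch = dst.extract_patch(s.ct, c, dst.CT_PATCH)
            mr_patch = dst.extract_patch(self._aligned_mr_cached(s), c, dst.MR_PATCH)
            truth = dst.TrabecularParams(row.bvtv, row.tbth_mm, row.tbsp_mm,
                                         row.tbn_per_mm) if with_truth else None
            pairs.append(dst.PatchPair(ct_patch, mr_patch, c, truth, row.subject_id))
        return pairs

    def _restore_state(self, stage: str) -> None:
        """Rebuild the in-memory state a skipped (hash-matched) stage provides."""
        if stage == "cohort" and self.subjects is None:
            spec = ph.CohortSpec(n_subjects=self.preset["n_subjects"],
                                 seed=self.cfg.seed, **self.cfg.cohort)
            self.subjects = ph.generate_cohort(spec)
        elif stage == "patch_pairs":
            self.pairs = self._rebuild_pairs(pd.read_csv(self.out / "patches.csv"),
                                             with_truth=False)
        elif stage == "morphometry_truth":
            self.pairs = self._rebuild_pairs(pd.read_csv(self.out / "patch_truth.csv"),
                                             with_truth=True)

    def _aligned_mr_cached(self, s: ph.CohortSubject) -> Volume3D:
        cache = getattr(self, "_mr_cache", {})
        if s.subject_id not in cache:
            cache[s.subject_id] = self._aligned_mr(s)
            self._mr_cache = cache
        return cache[s.subject_id]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig, resume: bool = False) -> RunManifest:
    """Execute the enabled stages in dependency order; see module docstring."""
    return _Run(config, resume).execute()


def ct_only_inference(run_dir, ct: Volume3D, trabecular_mask: Volume3D,
                      n_subregions: int | None = None) -> dict:
    """Patient-level readout from a CT volume alone (deployment path).

    Loads the trained student and aggregator from ``run_dir`` and runs
    subregion partitioning -> patch regression -> transformer aggregation.
    No MR data or registration artifact is touched.
    """
    run_dir = Path(run_dir)
    student = load_regression_model(run_dir / "student.npz")
    model = load_aggregator(run_dir / "aggregator.npz")
    if n_subregions is None:
        manifest = RunManifest.load(run_dir / "manifest.json")
        n_subregions = _SCALE_PRESETS[manifest.config["scale"]]["subregions"]
    centers = agg.partition_subregions(trabecular_mask, n_subregions)
    patches, kept = [], []
    for c in centers:
        patch = dst.extract_patch(ct, c, dst.CT_PATCH)
        if patch is not None:
            patches.append(patch)
            kept.append(c)
    preds = student.predict(np.array(patches))
    lo = np.asarray(ct.origin)
    record = agg.PatientRecord("ct_only", preds, np.array(kept),
                               bounds=(lo, lo + np.asarray(ct.extent_mm)))
    _, probs, score = agg.aggregate(model, record)
    return {"params": preds, "centers": np.array(kept),
            "p_normal": float(probs[0]), "p_mild": float(probs[1]),
            "p_advanced": float(probs[2]), "p_oa": float(probs[1] + probs[2]),
            "score_hat": score}
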