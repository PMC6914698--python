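"""End-to-end orchestration: generate -> fit DTI -> segment -> frequency map
-> statistics.

Two entry points:

* :func:`analyze_cohort` — fully in-memory pipeline on a simulated cohort;
  the workhorse behind the integration tests and the acceptance script.
* :func:`run_pipeline` — the on-disk staged pipeline behind the CLI, with
  per-stage config-hash caching (a stage is skipped when its config section
  is unchanged and all of its recorded outputs still exist, so editing only
  the stats options never re-runs the expensive DTI fits).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .dti import DwiDataset, fit_tensor_lls, fa_map
from .freqmap import (DEFAULT_EDGES_PERCENT, build_frequency_map,
                      bin_frequency_map, bin_voxel_counts, normative_fa_by_bin)
from .stats import analysis_report, write_report
from .synth import CohortConfig, generate_cohorts, simulate_cohort
from .wmhseg import (MaskSet, compute_lesion_stats, derive_nawm, dice,
                     normalize_intensity, segment_wmh)

__all__ = ["RunConfig", "analyze_cohort", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; round-trips through YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    segmentation_k: float = 1.2
    wm_restrict: bool = False      # intersect WMH masks with the WM mask
    use_true_masks: bool = False   # bypass segmentation with generator truth
    bin_edges_percent: tuple = DEFAULT_EDGES_PERCENT
    bin_overflow: bool = False
    ws_variant: str = "repeated"
    regression_direction: str = "volume_on_fa"
    out_dir: str = "wmhfreq_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["bin_edges_percent"] = [list(e) for e in self.bin_edges_percent]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        coh = dict(d.pop("cohort", {}))
        if "tissue_means" in coh:
            coh["tissue_means"] = {int(k): float(v)
                                   for k, v in coh["tissue_means"].items()}
        for key in ("shape", "voxel_size_mm"):
            if key in coh:
                coh[key] = tuple(coh[key])
        if "bin_edges_percent" in d:
            d["bin_edges_percent"] = tuple(tuple(e) for e in d["bin_edges_percent"])
        return cls(cohort=CohortConfig(**coh), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _subject_masks(cohort, run: RunConfig, i: int):
    """One older subject's truth mask and analysis (WMH, NAWM) masks."""
    truth = cohort.old_lesion_mask(i)
    anatomy = cohort.anatomy
    if run.use_true_masks:
        wmh = truth.copy()
    else:
        flair = cohort.old_flair(i, truth)
        norm = normalize_intensity(flair, anatomy.brain)
        wmh = segment_wmh(norm, anatomy.brain, k=run.segmentation_k)
    if run.wm_restrict:
        wmh = wmh & anatomy.white_matter
    nawm = derive_nawm(anatomy.white_matter, wmh)
    return truth, wmh, nawm


def analyze_cohort(config: CohortConfig, run: RunConfig | None = None) -> dict:
    """Simulate a cohort and run the complete analysis in memory.

    Returns the stats record from :func:`wmhfreq.stats.analysis_report`
    augmented with QC summaries (per-bin voxel counts, mean Dice of the
    segmentation against the generator truth, frequency-map maximum).
    """
    run = run or RunConfig(cohort=config)
    cohort = simulate_cohort(config)
    anatomy = cohort.anatomy

    wmh_masks, stats_rows, dices = [], [], []
    for i in range(config.n_old):
        truth, wmh, nawm = _subject_masks(cohort, run, i)
        dices.append(dice(wmh, truth))
        fa = fa_map(fit_tensor_lls(cohort.old_dwi(i, truth)))
        ms = MaskSet(brain=anatomy.brain, white_matter=anatomy.white_matter,
                     wmh=wmh, nawm=nawm, voxel_size_mm=config.voxel_size_mm)
        ls = compute_lesion_stats(fa, ms)
        stats_rows.append({"subject_id": f"old{i:04d}", **asdict(ls)})
        wmh_masks.append(wmh)

    freq = build_frequency_map(wmh_masks, voxel_size_mm=config.voxel_size_mm)
    bins = bin_frequency_map(freq, edges_percent=run.bin_edges_percent,
                             overflow=run.bin_overflow)
    young_fa = [fa_map(fit_tensor_lls(cohort.young_dwi(j)))
                for j in range(config.n_young)]
    bin_matrix = normative_fa_by_bin(young_fa, bins)

    lesion_df = pd.DataFrame(stats_rows)
    report = analysis_report(lesion_df, bin_matrix,
                             ws_variant=run.ws_variant,
                             regression_direction=run.regression_direction)
    report["qc"] = {
        "bin_voxel_counts": bin_voxel_counts(bins).to_dict(),
        "mean_dice_vs_truth": float(np.mean(dices)),
        "frequency_max_percent": float(100.0 * freq.f.max()),
        "n_wm_voxels": int(anatomy.white_matter.sum()),
    }
    report["lesion_stats"] = lesion_df.to_dict(orient="list")
    report["bin_matrix"] = {c: bin_matrix[c].tolist() for c in bin_matrix.columns}
    return report


# ---------------------------------------------------------------------------
# on-disk staged pipeline


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


class _Stages:
    """Per-stage cache records under <out>/_stages/<name>.json."""

    def __init__(self, root: Path):
        self.dir = root / "_stages"
        self.dir.mkdir(parents=True, exist_ok=True)

    def fresh(self, name: str, cfg_hash: str) -> bool:
        rec = self.dir / f"{name}.json"
        if not rec.exists():
            return False
        data = json.loads(rec.read_text())
        if data.get("hash") != cfg_hash:
            return False
        return all(Path(p).exists() for p in data.get("outputs", []))

    def record(self, name: str, cfg_hash: str, outputs: list) -> None:
        (self.dir / f"{name}.json").write_text(json.dumps(
            {"hash": cfg_hash, "outputs": [str(p) for p in outputs],
             "time": time.time()}, indent=2))


def run_pipeline(run: RunConfig, log=print) -> dict:
    """Execute all stages on disk; returns the run manifest (paths per stage).

    Deterministic end-to-end given the config seed. A failing stage raises
    :class:`StageError` naming the stage; upstream outputs stay on disk.
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _Stages(out)
    cfg = run.to_dict()
    run.to_yaml(out / "config.yaml")
    manifest: dict = {"config_hash": _hash(cfg), "stages": {}}
    cohort = simulate_cohort(run.cohort)
    anatomy = cohort.anatomy
    vs = run.cohort.voxel_size_mm

    # -- generate ----------------------------------------------------------
    gen_hash = _hash(cfg["cohort"])
    data_dir = out / "data"
    if stages.fresh("generate", gen_hash):
        log("[generate] cached")
        files = wio.read_manifest(data_dir / "manifest.tsv")
    else:
        try:
            files = generate_cohorts(run.cohort, data_dir)
        except Exception as exc:
            raise StageError("generate", exc) from exc
        stages.record("generate", gen_hash, files["path"].tolist())
        log(f"[generate] wrote {len(files)} files")
    manifest["stages"]["generate"] = str(data_dir / "manifest.tsv")

    # -- fit-dti -----------------------------------------------------------
    fit_hash = _hash([cfg["cohort"]])
    fa_dir = out / "fa"
    fa_dir.mkdir(exist_ok=True)
    old_fa = [fa_dir / f"old{i:04d}_fa.nii" for i in range(run.cohort.n_old)]
    young_fa = [fa_dir / f"young{j:04d}_fa.nii" for j in range(run.cohort.n_young)]
    if stages.fresh("fit-dti", fit_hash):
        log("[fit-dti] cached")
    else:
        try:
            n_clamped = 0
            for i, path in enumerate(old_fa):
                tf = fit_tensor_lls(cohort.old_dwi(i))
                n_clamped += tf.n_clamped_signals
                wio.save_volume(path, fa_map(tf), vs, dtype=np.float32)
            for j, path in enumerate(young_fa):
                tf = fit_tensor_lls(cohort.young_dwi(j))
                n_clamped += tf.n_clamped_signals
                wio.save_volume(path, fa_map(tf), vs, dtype=np.float32)
        except Exception as exc:
            raise StageError("fit-dti", exc) from exc
        stages.record("fit-dti", fit_hash, old_fa + young_fa)
        log(f"[fit-dti] {len(old_fa) + len(young_fa)} FA maps, "
            f"{n_clamped} signals floored")
    manifest["stages"]["fit-dti"] = str(fa_dir)

    # -- segment -----------------------------------------------------------
    seg_hash = _hash([cfg["cohort"], run.segmentation_k, run.wm_restrict,
                      run.use_true_masks])
    seg_dir = out / "masks"
    seg_dir.mkdir(exist_ok=True)
    wmh_paths = [seg_dir / f"old{i:04d}_wmh.nii" for i in range(run.cohort.n_old)]
    nawm_paths = [seg_dir / f"old{i:04d}_nawm.nii" for i in range(run.cohort.n_old)]
    if stages.fresh("segment", seg_hash):
        log("[segment] cached")
    else:
        try:
            dices = []
            for i in range(run.cohort.n_old):
                truth, wmh, nawm = _subject_masks(cohort, run, i)
                dices.append(dice(wmh, truth))
                wio.save_volume(wmh_paths[i], wmh.astype(np.uint8), vs, dtype=np.uint8)
                wio.save_volume(nawm_paths[i], nawm.astype(np.uint8), vs, dtype=np.uint8)
        except Exception as exc:
            raise StageError("segment", exc) from exc
        stages.record("segment", seg_hash, wmh_paths + nawm_paths)
        log(f"[segment] {run.cohort.n_old} subjects, "
            f"mean Dice vs truth {np.mean(dices):.3f}")
    manifest["stages"]["segment"] = str(seg_dir)

    # -- freqmap -----------------------------------------------------------
    freq_hash = _hash([seg_hash, list(map(list, run.bin_edges_percent)),
                       run.bin_overflow])
    freq_dir = out / "freq"
    freq_dir.mkdir(exist_ok=True)
    freq_path = freq_dir / "wmh_frequency.nii"
    counts_path = freq_dir / "bin_voxel_counts.tsv"
    if stages.fresh("freqmap", freq_hash):
        log("[freqmap] cached")
        masks = [wio.load_mask(p) for p in wmh_paths]
        freq = build_frequency_map(masks, vs)
        bins = bin_frequency_map(freq, run.bin_edges_percent, run.bin_overflow)
    else:
        try:
            masks = [wio.load_mask(p) for p in wmh_paths]
            freq = build_frequency_map(masks, vs)
            bins = bin_frequency_map(freq, run.bin_edges_percent, run.bin_overflow)
            wio.save_volume(freq_path, freq.f, vs, dtype=np.float32,
                            description="WMH frequency (fraction of subjects)")
            outputs = [freq_path, counts_path]
            for lab, m in zip(bins.labels, bins.bin_masks):
                p = freq_dir / f"bin_{lab.replace('%', '').replace('-', '_')}.nii"
                wio.save_volume(p, m.astype(np.uint8), vs, dtype=np.uint8)
                outputs.append(p)
            bin_voxel_counts(bins).to_csv(counts_path, sep="\t")
        except Exception as exc:
            raise StageError("freqmap", exc) from exc
        stages.record("freqmap", freq_hash, outputs)
        log(f"[freqmap] max frequency {100 * freq.f.max():.1f}%, "
            f"bin counts {bin_voxel_counts(bins).tolist()}")
    manifest["stages"]["freqmap"] = str(freq_dir)

    # -- analyze -----------------------------------------------------------
    ana_hash = _hash([freq_hash, fit_hash, run.ws_variant, run.regression_direction])
    ana_dir = out / "analysis"
    ana_dir.mkdir(exist_ok=True)
    report_json = ana_dir / "report.json"
    if stages.fresh("analyze", ana_hash):
        log("[analyze] cached")
    else:
        try:
            rows = []
            for i in range(run.cohort.n_old):
                fa, _ = wio.load_volume(old_fa[i])
                ms = MaskSet(brain=anatomy.brain, white_matter=anatomy.white_matter,
                             wmh=wio.load_mask(wmh_paths[i]),
                             nawm=wio.load_mask(nawm_paths[i]), voxel_size_mm=vs)
                rows.append({"subject_id": f"old{i:04d}",
                             **asdict(compute_lesion_stats(fa, ms))})
            lesion_df = pd.DataFrame(rows)
            lesion_df.to_csv(ana_dir / "lesion_stats.tsv", sep="\t", index=False)
            young_maps = [wio.load_volume(p)[0] for p in young_fa]
            bin_matrix = normative_fa_by_bin(young_maps, bins)
            bin_matrix.to_csv(ana_dir / "bin_matrix.tsv", sep="\t", index=False)
            report = analysis_report(lesion_df, bin_matrix,
                                     ws_variant=run.ws_variant,
                                     regression_direction=run.regression_direction)
            write_report(report, report_json, ana_dir / "report.txt")
        except Exception as exc:
            raise StageError("analyze", exc) from exc
        stages.record("analyze", ana_hash,
                      [report_json, ana_dir / "report.txt",
                       ana_dir / "lesion_stats.tsv", ana_dir / "bin_matrix.tsv"])
        log("[analyze] report written")
    manifest["stages"]["analyze"] = str(report_json)

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_inputs(manifest_path) -> list:
    """Check a generated dataset; returns a list of violation strings.

    Verifies NIfTI readability, grid agreement across the cohort, gradient
    table vs DWI volume-count agreement, and mask binarity.
    """
    violations = []
    try:
        files = wio.read_manifest(manifest_path)
    except Exception as exc:
        return [f"manifest unreadable: {exc}"]
    root = Path(manifest_path).parent
    shapes = {}
    for _, row in files.iterrows():
        if row["modality"] in ("bvals", "bvecs"):
            continue
        path = Path(row["path"])
        if not path.is_absolute():
            path = root / path
        try:
            data, _ = wio.load_volume(path)
        except Exception as exc:
            violations.append(f"{path}: unreadable NIfTI ({exc})")
            continue
        shapes[str(path)] = data.shape[:3]
        if row["modality"] in ("lesion_mask", "brain_mask", "wm_mask"):
            bad = np.count_nonzero(~np.isin(data, (0, 1)))
            if bad:
                violations.append(f"{path}: {bad} non-binary mask voxels")
        if row["modality"] == "dwi":
            sid = row["subject_id"]
            bv = root / f"{sid}.bval"
            gv = root / f"{sid}.bvec"
            try:
                bvals, bvecs = wio.read_gradient_table(bv, gv)
                if data.ndim != 4 or data.shape[3] != len(bvals):
                    nvol = data.shape[3] if data.ndim == 4 else 1
                    violations.append(
                        f"{path}: {nvol} volumes but {len(bvals)} b-values")
            except Exception as exc:
                violations.append(f"{sid}: gradient table problem ({exc})")
    if len(set(shapes.values())) > 1:
        violations.append(f"grid disagreement across cohort: {set(shapes.values())}")
    return violations
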