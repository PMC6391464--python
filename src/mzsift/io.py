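"""File formats, configuration, and pipeline orchestration.

Run files use a plain columnar text dialect (CSV of scan index, retention
time, m/z to 6 decimals, intensity, with a commented metadata header) that
round-trips losslessly at that precision; centroided mzML is supported
read-only through pyteomics. Feature tables, verdicts, comparison tables,
drift reports, multivariate exports and the annotation table are CSV.

`run_pipeline` chains the stages in the workflow's order — simulate (or
load) -> peak picking -> significance filtering on raw abundances ->
zero-replacement + log10 -> QC drift correction -> PCA / t-SNE /
hierarchical clustering -> annotation — and emits a manifest (seed, config
hash, per-stage feature counts, timings) so the survivor accounting of each
filter is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from . import drift as _drift
from . import mva as _mva
from . import peaks as _peaks
from . import simulate as _simulate
from . import stats as _stats
from .chem import ElementalFormula
from .spectra import SpectrumRun
from .table import FeatureTable

__all__ = ["write_run", "read_run", "read_mzml", "PipelineConfig",
           "PipelineResult", "run_pipeline"]


# ---------------------------------------------------------------------------
# run files

def write_run(run: SpectrumRun, path: str | Path) -> None:
    """Write a centroided run in the columnar text dialect."""
    path = Path(path)
    grid = run.scan_times
    with path.open("w") as fh:
        meta = {"sample_id": run.sample_id, "group": run.group,
                "sample_type": run.sample_type,
                "injection_index": run.injection_index,
                "polarity": run.polarity,
                "rt_start": float(grid[0]),
                "scan_interval": run.scan_interval,
                "n_scans": run.n_scans}
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("scan,rt,mz,intensity\n")
        for i, (mz, inten) in enumerate(run.scans):
            t = grid[i]
            for m, it in zip(mz, inten):
                fh.write(f"{i},{t:.3f},{m:.6f},{it:.6g}\n")


def read_run(path: str | Path) -> SpectrumRun:
    """Read a columnar-text run written by :func:`write_run`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                meta[k.strip()] = v.strip()
            elif not line.startswith("scan,"):
                rows.append(line)
    if "n_scans" not in meta:
        raise ValueError(f"{path}: missing metadata header (empty or foreign file)")
    n_scans = int(meta["n_scans"])
    if n_scans == 0:
        raise ValueError(f"{path}: empty run (no scans)")
    grid = float(meta["rt_start"]) + np.arange(n_scans) * float(meta["scan_interval"])
    per_mz: list[list[float]] = [[] for _ in range(n_scans)]
    per_int: list[list[float]] = [[] for _ in range(n_scans)]
    for line in rows:
        si, _, m, it = line.split(",")
        per_mz[int(si)].append(float(m))
        per_int[int(si)].append(float(it))
    scans = []
    for mzs, ints in zip(per_mz, per_int):
        mz = np.asarray(mzs)
        it = np.asarray(ints)
        order = np.argsort(mz)
        scans.append((mz[order], it[order]))
    return SpectrumRun(sample_id=meta["sample_id"], group=meta["group"],
                       sample_type=meta["sample_type"],
                       injection_index=int(meta["injection_index"]),
                       polarity=meta["polarity"], scan_times=grid,
                       scans=scans)


def _decode_binary_array(node) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, optional zlib)."""
    import base64
    import zlib

    accessions = {c.get("accession") for c in node
                  if c.tag.endswith("cvParam")}
    binary = next(c for c in node if c.tag.endswith("binary"))
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path, sample_id: str | None = None,
              group: str = "", sample_type: str = "incubation",
              injection_index: int = 0) -> SpectrumRun:
    """Read a centroided mzML file (MS1 scans) into a SpectrumRun.

    A self-contained reader for the mzML subset this pipeline consumes:
    MS1 spectra with 32/64-bit float m/z and intensity arrays, optionally
    zlib-compressed; scan start times in seconds or minutes. Profile-mode
    spectra are rejected — the pipeline operates on centroids.
    """
    from lxml import etree

    path = Path(path)
    times, scans = [], []
    polarity = "pos"
    for _, spec in etree.iterparse(str(path),
                                   tag="{*}spectrum"):
        cv = {c.get("accession"): c for c in spec.iter("{*}cvParam")}
        level = cv.get("MS:1000511")
        if level is not None and level.get("value") not in ("1", "", None):
            spec.clear()
            continue
        if "MS:1000128" in cv:  # profile spectrum
            raise ValueError(
                f"{path}: profile-mode spectra are unsupported; "
                "centroid the data first")
        if "MS:1000129" in cv:  # negative scan
            polarity = "neg"
        t = 0.0
        rt_node = cv.get("MS:1000016")
        if rt_node is not None:
            t = float(rt_node.get("value"))
            unit = (rt_node.get("unitName") or "").lower()
            if unit.startswith("min"):
                t *= 60.0
        mz = inten = None
        for arr in spec.iter("{*}binaryDataArray"):
            arr_cv = {c.get("accession") for c in arr
                      if c.tag.endswith("cvParam")}
            if "MS:1000514" in arr_cv:
                mz = _decode_binary_array(arr)
            elif "MS:1000515" in arr_cv:
                inten = _decode_binary_array(arr)
        if mz is not None and inten is not None:
            order = np.argsort(mz)
            times.append(t)
            scans.append((mz[order], inten[order]))
        spec.clear()
    if not times:
        raise ValueError(f"{path}: no MS1 spectra found")
    order = np.argsort(times)
    return SpectrumRun(sample_id=sample_id or path.stem, group=group,
                       sample_type=sample_type,
                       injection_index=injection_index, polarity=polarity,
                       scan_times=np.asarray(times)[order],
                       scans=[scans[i] for i in order])


# ---------------------------------------------------------------------------
# configuration

def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class ScenarioConfig:
    n_background: int = 200
    replicates: int = 5
    qc_lead_in: int = 5
    qc_every: int = 5
    blank_duplicates: int = 2
    drift_rate: float = -0.004
    sigma_ppm: float = 1.0
    bio_cv: float = 0.05
    tech_cv: float = 0.02
    noise_per_scan: float = 15.0
    noise_level: float = 30.0
    carryover_prob: float = 0.25


@dataclass
class PickingConfig:
    ppm_tol: float = 5.0
    min_scans: int = 5
    snr_min: float = 5.0
    rt_tol_s: float = 10.0
    width_min_s: float = 2.0
    width_max_s: float = 60.0


@dataclass
class FilterConfig:
    fc_thresh: float = 1.5
    p_thresh: float = 0.001
    rt_min_s: float = 60.0
    rt_max_s: float = 600.0
    fdr: bool = False


@dataclass
class DriftConfig:
    piecewise: bool = False
    exclude_qc: list[str] = field(default_factory=list)


@dataclass
class MvaConfig:
    perplexity: float = 5.0
    tsne_seed: int = 42
    linkage_method: str = "complete"
    metric: str = "euclidean"


@dataclass
class AnnotationConfig:
    parent_formula: str = "C14H19NO"
    ppm_tol: float = 5.0
    rt_tol_s: float = 5.0
    isomer_rt_tol_s: float = 10.0
    blank_presence_factor: float = 3.0


@dataclass
class PipelineConfig:
    """All pipeline parameters with the workflow's defaults
    (fold change 1.5, p 0.001, RT window [60, 600] s, 5 ppm)."""

    seed: int = 0
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    picking: PickingConfig = field(default_factory=PickingConfig)
    filtering: FilterConfig = field(default_factory=FilterConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    mva: MvaConfig = field(default_factory=MvaConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {"scenario": ScenarioConfig, "picking": PickingConfig,
                    "filtering": FilterConfig, "drift": DriftConfig,
                    "mva": MvaConfig, "annotation": AnnotationConfig}
        kwargs: dict = {}
        for key, sub_cls in sections.items():
            if key in data:
                kwargs[key] = _from_mapping(sub_cls, data.pop(key))
        if "seed" in data:
            kwargs["seed"] = int(data.pop("seed"))
        if data:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable hash of the resolved configuration (seed included)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def build_scenario(self) -> _simulate.Scenario:
        sc = self.scenario
        design = _simulate.SequenceDesign(
            replicates=sc.replicates, qc_lead_in=sc.qc_lead_in,
            qc_every=sc.qc_every, blank_duplicates=sc.blank_duplicates,
            drift_rate=sc.drift_rate)
        noise = _simulate.NoiseModel(
            sigma_ppm=sc.sigma_ppm, bio_cv=sc.bio_cv, tech_cv=sc.tech_cv,
            noise_per_scan=sc.noise_per_scan, noise_level=sc.noise_level,
            carryover_prob=sc.carryover_prob)
        return _simulate.default_scenario(design=design, noise=noise,
                                          n_background=sc.n_background)


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one pipeline execution."""

    config: PipelineConfig
    study: _simulate.Study | None
    table_raw: FeatureTable
    filtered_raw: FeatureTable
    verdicts: pd.DataFrame
    comparisons: pd.DataFrame
    transformed: FeatureTable
    drift_models: list[_drift.DriftModel]
    corrected: FeatureTable
    pca: _mva.PcaResult
    embedding: pd.DataFrame
    clustering: _mva.ClusterResult
    annotations: dict[str, _annotate.Annotation]
    annotation_df: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table_raw.to_csv(out / "feature_table.csv")
        self.verdicts.to_csv(out / "verdicts.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        self.corrected.to_csv(out / "corrected_table.csv")
        self.pca.scores.to_csv(out / "pca_scores.csv")
        self.pca.loadings.to_csv(out / "pca_loadings.csv")
        pd.DataFrame({"component": [f"PC{i+1}" for i in
                                    range(len(self.pca.variance_explained))],
                      "variance_pct": self.pca.variance_explained}
                     ).to_csv(out / "pca_variance.csv", index=False)
        self.embedding.to_csv(out / "tsne.csv")
        self.clustering.zscores.to_csv(out / "cluster_zscores.csv")
        self.annotation_df.to_csv(out / "annotations.csv", index=False)
        if self.study is not None:
            self.study.ledger.to_csv(out / "ledger.csv", index=False)
        with (out / "manifest.json").open("w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig | None = None,
                 study: _simulate.Study | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow.

    With no ``study`` given, the default synthetic scenario is simulated
    from ``config.seed``. All randomness (simulation, t-SNE) flows from the
    config; identical config + seed gives identical CSV outputs.
    """
    config = config or PipelineConfig()
    manifest: dict = {"seed": config.seed, "config_hash": config.hash(),
                      "stages": {}}
    timings: dict[str, float] = {}

    def stage(name: str):
        timings[name] = time.perf_counter()

    def done(name: str, **counts) -> None:
        timings[name] = time.perf_counter() - timings[name]
        manifest["stages"][name] = {"seconds": round(timings[name], 3),
                                    **counts}

    try:
        stage("simulate")
        if study is None:
            study = _simulate.simulate_study(config.build_scenario(),
                                             seed=config.seed)
        done("simulate", n_runs=len(study.runs),
             n_planted=int(study.ledger["species"].nunique())
             if len(study.ledger) else 0)

        stage("peaks")
        pk = config.picking
        table = _peaks.pick_study(
            study.runs, study.samples, ppm_tol=pk.ppm_tol,
            min_scans=pk.min_scans, snr_min=pk.snr_min,
            rt_tol_s=pk.rt_tol_s,
            width_bounds_s=(pk.width_min_s, pk.width_max_s))
        done("peaks", n_features=len(table.feature_names))

        stage("stats")
        fl = config.filtering
        filtered, verdicts, comparisons = _stats.apply_filters(
            table, fc_thresh=fl.fc_thresh, p_thresh=fl.p_thresh,
            rt_window=(fl.rt_min_s, fl.rt_max_s), fdr=fl.fdr)
        done("stats", n_in=len(table.feature_names),
             n_significant=len(filtered.feature_names))

        stage("transform")
        transformed = _stats.transform_abundances(filtered)
        done("transform")

        stage("drift")
        models = _drift.fit_drift(transformed,
                                  exclude_qc=config.drift.exclude_qc or None)
        corrected = _drift.correct(transformed, models,
                                   piecewise=config.drift.piecewise)
        done("drift", n_eligible=sum(m.eligible for m in models))

        stage("mva")
        # pattern analysis covers the statistical sequence (incubation
        # replicates + pooled QCs); the blank identification runs are
        # evidence for annotation, not part of the multivariate view
        seq_ids = [s for s, t in corrected.samples["sample_type"].items()
                   if t in ("incubation", "qc")]
        mva_input = corrected.subset_samples(seq_ids)
        pca_res = _mva.pca(mva_input)
        emb = _mva.tsne(mva_input, perplexity=config.mva.perplexity,
                        seed=config.mva.tsne_seed)
        clus = _mva.hclust_heatmap(mva_input,
                                   method=config.mva.linkage_method,
                                   metric=config.mva.metric)
        done("mva", pc1_variance_pct=round(float(
            pca_res.variance_explained[0]), 3))

        stage("annotate")
        dose_responsive = {
            r.feature for r in comparisons.itertuples(index=False)
            if r.pair == "Blank-High" and r.p_value < fl.p_thresh
            and (np.isposinf(r.fold_change)
                 or (np.isfinite(r.fold_change)
                     and r.fold_change > fl.fc_thresh))}
        ac = config.annotation
        annotations = _annotate.annotate_features(
            filtered, ElementalFormula.parse(ac.parent_formula),
            dose_responsive=dose_responsive,
            noise_floor=study.noise_floor,
            blank_presence_factor=ac.blank_presence_factor,
            ppm_tol=ac.ppm_tol, rt_tol_s=ac.rt_tol_s,
            isomer_rt_tol_s=ac.isomer_rt_tol_s)
        ann_df = _annotate.annotation_table(
            annotations, filtered, polarity=study.scenario.polarity)
        done("annotate", n_annotated=sum(
            1 for a in annotations.values() if a.class_label != "unknown"))
    except Exception as exc:  # noqa: BLE001 - rethrow with stage context
        failed = [k for k, v in timings.items()
                  if not isinstance(v, float) or k not in manifest["stages"]]
        name = failed[-1] if failed else "unknown"
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    result = PipelineResult(
        config=config, study=study, table_raw=table, filtered_raw=filtered,
        verdicts=verdicts, comparisons=comparisons, transformed=transformed,
        drift_models=models, corrected=corrected, pca=pca_res, embedding=emb,
        clustering=clus, annotations=annotations, annotation_df=ann_df,
        manifest=manifest)
    if out_dir is not None:
        result.write(out_dir)
    return result
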