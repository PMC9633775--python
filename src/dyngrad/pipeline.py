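"""End-to-end orchestration: simulate → gradients → arousal → dynamics → GLM → receptors → surrogates.

A PipelineConfig (TOML-loadable) carries input paths, the analysis
parameters and per-stage toggles; run_pipeline executes the enabled stages
in order, writes every table as TSV with a JSON summary per stage, and
records a manifest (config, seeds, output hashes) so identical configs
reproduce identical outputs. One global seed fans out to per-stage seeds by
deterministic hashing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arousal as ar
from . import dynamics as dyn
from . import glm as glm_mod
from . import gradients as gr
from . import similarity as sim
from . import surrogates as surr
from . import synth
from ._utils import spawn_seed
from .containers import RegionTimeSeries

__all__ = ["PipelineConfig", "run_pipeline", "write_cohort", "load_scans"]

STAGES = ("simulate", "gradients", "arousal", "dynamics", "glm", "receptors", "surrogates")


@dataclass
class PipelineConfig:
    outdir: str = "dyngrad_out"
    seed: int = 0
    # input paths (used when simulate is off)
    scans_dir: str | None = None
    pupil_dir: str | None = None
    tracing_path: str | None = None
    expression_path: str | None = None
    coords_path: str | None = None
    tr: float = 2.0
    fps: int = 6
    # analysis parameters
    density: float = 0.10
    n_components: int = 5
    n_bins: int = 10
    n_shuffles: int = 1000
    n_surrogates: int = 1000
    ridge: float = 1e-6
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    cohort: dict = field(default_factory=dict)  # synth.DEFAULTS overrides for simulate

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        stages = {s: True for s in STAGES}
        stages.update(raw.pop("stages", {}))
        cohort = raw.pop("cohort", {})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(stages=stages, cohort=cohort, **raw)

    def validate(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.n_bins < 2 or self.n_components < 1:
            raise ValueError("n_bins ≥ 2 and n_components ≥ 1 required")
        if not self.stages.get("simulate", False):
            for key in ("scans_dir", "tracing_path", "expression_path", "coords_path"):
                p = getattr(self, key)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config.{key} missing or does not exist: {p}")


def _write_tsv(path: Path, array: np.ndarray, labels=None, index=None) -> None:
    pd.DataFrame(array, columns=labels, index=index).to_csv(path, sep="\t", index=index is not None)


def write_cohort(cohort: synth.SyntheticCohort, outdir: str | Path) -> Path:
    """Write a synthetic cohort as the TSV inputs the pipeline consumes."""
    out = Path(outdir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    (out / "pupil").mkdir(exist_ok=True)
    for i, ts in enumerate(cohort.scans):
        _write_tsv(out / "scans" / f"scan{i:03d}.tsv", ts.data, labels=ts.labels)
    for i, tr_p in enumerate(cohort.pupil_traces):
        _write_tsv(out / "pupil" / f"pupil{i:03d}.tsv", tr_p[:, None], labels=["pupil"])
    _write_tsv(
        out / "tracing.tsv",
        cohort.tracing.weights,
        labels=cohort.tracing.target_labels,
        index=cohort.tracing.source_labels,
    )
    _write_tsv(
        out / "expression.tsv",
        cohort.expression.values,
        labels=[f"R{i:03d}" for i in range(cohort.expression.n_regions)],
        index=cohort.expression.receptor_labels,
    )
    _write_tsv(out / "coords.tsv", cohort.truth.coords, labels=["x", "y"])
    manifest = "\n".join(
        [
            "# dyngrad synthetic-cohort manifest",
            f'tr = {cohort.tr}',
            f'fps = {cohort.fps}',
            f'n_scans = {len(cohort.scans)}',
            f'n_regions = {cohort.scans[0].n_regions}',
        ]
    )
    (out / "manifest.toml").write_text(manifest + "\n")
    return out


def load_scans(scans_dir: str | Path, tr: float) -> list[RegionTimeSeries]:
    files = sorted(Path(scans_dir).glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no scan TSVs in {scans_dir}")
    return [RegionTimeSeries(pd.read_csv(f, sep="\t").to_numpy(), tr=tr) for f in files]


def _hash_dir(out: Path) -> dict[str, str]:
    hashes = {}
    for f in sorted(out.rglob("*.tsv")) + sorted(out.rglob("*.json")):
        hashes[str(f.relative_to(out))] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
    return hashes


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the summary dictionary.

    Outputs land under config.outdir; `summary.json` aggregates the headline
    numbers of every stage that ran.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    on = config.stages
    summary: dict = {"seed": config.seed}

    cohort = None
    if on.get("simulate", True):
        cohort = synth.make_cohort(seed=spawn_seed(config.seed, "simulate"), **config.cohort)
        write_cohort(cohort, out / "inputs")
        scans = cohort.scans
        pupils = cohort.pupil_traces
        tracing = cohort.tracing
        expression = cohort.expression
        coords = cohort.truth.coords
        tr, fps = cohort.tr, cohort.fps
    else:
        tr, fps = config.tr, config.fps
        scans = load_scans(config.scans_dir, tr)
        pupils = [
            pd.read_csv(f, sep="\t")["pupil"].to_numpy()
            for f in sorted(Path(config.pupil_dir).glob("*.tsv"))
        ]
        tdf = pd.read_csv(config.tracing_path, sep="\t", index_col=0)
        tracing = synth.DirectedTracingMatrix(
            tdf.to_numpy(), list(tdf.index), list(tdf.columns)
        )
        edf = pd.read_csv(config.expression_path, sep="\t", index_col=0)
        expression = synth.ExpressionMatrix(edf.to_numpy(), list(edf.index))
        coords = pd.read_csv(config.coords_path, sep="\t").to_numpy()

    # ---- static gradients ----------------------------------------------
    reference = None
    if on.get("gradients", True):
        fcs = [gr.compute_fc(ts) for ts in scans]
        study_fc = gr.ConnectivityMatrix(np.mean([c.values for c in fcs], axis=0))
        reference = gr.gradients_from_connectivity(
            study_fc, n_components=config.n_components, density=config.density
        )
        aligned = [
            gr.procrustes_align(
                gr.gradients_from_connectivity(
                    c, n_components=config.n_components, density=config.density
                ),
                reference,
            )
            for c in fcs
        ]
        _write_tsv(
            out / "gradients.tsv",
            reference.components,
            labels=[f"G{k+1}" for k in range(reference.n_components)],
        )
        (out / "gradients.json").write_text(
            json.dumps(
                {
                    "eigenvalues": reference.eigenvalues.tolist(),
                    "explained_variance": reference.explained_variance.tolist(),
                    "scanwise_order_match": [
                        gr.fingerprint_similarity(a, reference, min(2, config.n_components))[1]
                        for a in aligned
                    ],
                },
                indent=2,
            )
        )
        summary["explained_variance_pct"] = (reference.explained_variance * 100).round(2).tolist()

    # ---- arousal --------------------------------------------------------
    fmri_idx = None
    if on.get("arousal", True):
        beh = [ar.behavioral_index(p, fps, tr) for p in pupils]
        template = ar.arousal_template(scans, beh)
        fmri_idx = [ar.fmri_arousal_index(ts, template) for ts in scans]
        _write_tsv(out / "arousal_template.tsv", template.map[:, None], labels=["template"])
        _write_tsv(
            out / "arousal_index.tsv",
            np.column_stack([np.concatenate([b.index for b in beh]),
                             np.concatenate([f.index for f in fmri_idx])]),
            labels=["behavioral", "fmri"],
        )
        summary["eye_open_ratio"] = [b.eye_open_ratio for b in beh]

    # ---- dynamics -------------------------------------------------------
    bin_mats = None
    if on.get("dynamics", True):
        if reference is None or fmri_idx is None:
            raise ValueError("dynamics stage needs gradients and arousal stages enabled")
        dccs = [dyn.dcc_fit(ts) for ts in scans]
        frames = np.concatenate([d[1].frames for d in dccs])
        index_all = np.concatenate([f.index for f in fmri_idx])
        assign = ar.bin_by_arousal(index_all, n_bins=config.n_bins)
        bin_mats = dyn.binned_mean_dfc(frames, assign)
        bin_grads = dyn.dynamic_gradients(bin_mats, reference, density=config.density)
        ev = np.array([g.explained_variance for g in bin_grads])
        trend = dyn.quadratic_trend(np.arange(config.n_bins, dtype=float) / (config.n_bins - 1), ev[:, 0])
        entropy = [dyn.fc_entropy(c) for c in bin_mats]
        _write_tsv(out / "bin_explained_variance.tsv", ev,
                   labels=[f"G{k+1}" for k in range(ev.shape[1])])
        summary["dynamics"] = {
            "dcc_ab_mean": [float(np.mean([p.a for p, _ in dccs])), float(np.mean([p.b for p, _ in dccs]))],
            "g1_ev_trend_shape": trend.shape,
            "g1_ev_quadratic": float(trend.coefficients[0]),
            "fc_entropy_per_bin": [float(e) for e in entropy],
        }

    # ---- GLM ------------------------------------------------------------
    sc_vec = ns_vec = None
    if on.get("glm", True):
        sc_sim = sim.tracing_similarity(tracing)
        ns_sim = sim.expression_similarity(expression)
        sc_vec = glm_mod.vectorize_pairs(sc_sim)
        ns_vec = glm_mod.vectorize_pairs(ns_sim)
        fc_vecs = np.array([glm_mod.vectorize_pairs(gr.compute_fc(ts)) for ts in scans])
        part = glm_mod.variance_partition(
            fc_vecs,
            {"SC": sc_vec, "NS": ns_vec},
            n_shuffles=config.n_shuffles,
            seed=spawn_seed(config.seed, "glm"),
            ridge=config.ridge,
        )
        summary["glm"] = {
            "cv_r2_full": part.cv_r2_full,
            "cv_r2_single": part.cv_r2_single,
            "delta_r2": part.delta_r2,
        }
        if bin_mats is not None:
            binned = glm_mod.binned_delta_r2(
                bin_mats,
                {"SC": sc_vec, "NS": ns_vec},
                n_shuffles=min(config.n_shuffles, 200),
                seed=spawn_seed(config.seed, "glm-binned"),
                ridge=config.ridge,
            )
            summary["glm"]["binned_delta_r2"] = {
                k: v.tolist() for k, v in binned["delta_r2"].items()
            }

    # ---- receptor contributions ----------------------------------------
    if on.get("receptors", True) and bin_mats is not None and sc_vec is not None:
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(np.asarray(coords)))
        rec_summary = {}
        pvals, names = [], []
        for rec in expression.receptor_labels:
            contrib = glm_mod.receptor_contribution(
                bin_mats,
                expression,
                rec,
                sc_vec,
                n_shuffles=config.n_surrogates,
                distance_matrix=dmat,
                seed=spawn_seed(config.seed, "receptor", rec),
                ridge=config.ridge,
            )
            r, _p_slope = surr.receptor_significance(
                contrib["similarity_to_empirical"], contrib["r2_surrogate"].mean(axis=1)
            )
            # calibrated significance: rank of the empirical fit in the
            # SA-surrogate null (exchangeability), right-tailed
            p = surr.sa_pvalue(
                float(contrib["r2_full_per_bin"].mean()),
                contrib["r2_surrogate"].mean(axis=1),
                tail="right",
            )
            rec_summary[rec] = {"delta_overall": contrib["delta_overall"], "r": r, "p": p}
            pvals.append(p)
            names.append(rec)
        reject, adj = surr.fdr_bh(np.array(pvals), q=0.05)
        for i, rec in enumerate(names):
            rec_summary[rec]["p_fdr"] = float(adj[i])
            rec_summary[rec]["significant"] = bool(reject[i])
        pca = sim.receptor_pca(expression, n_pc=min(3, expression.n_receptors))
        summary["receptors"] = rec_summary
        summary["receptor_pca_evr"] = pca["explained_variance_ratio"].tolist()

    # ---- SA-corrected structure-function similarity --------------------
    if on.get("surrogates", True) and reference is not None:
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(np.asarray(coords)))
        sc_sim2 = sim.tracing_similarity(tracing)
        sc_grad = gr.gradients_from_connectivity(
            sc_sim2, n_components=config.n_components, density=config.density
        )
        sc_g1 = gr.procrustes_align(sc_grad, reference).components[:, 0]
        fc_g1 = reference.components[:, 0]
        obs = abs(np.corrcoef(sc_g1, fc_g1)[0, 1])
        ens = surr.make_surrogates(
            sc_g1, dmat, n_surrogates=config.n_surrogates,
            seed=spawn_seed(config.seed, "surrogates"),
        )
        null = np.abs(
            (ens.maps - ens.maps.mean(1, keepdims=True))
            @ (fc_g1 - fc_g1.mean())
            / (np.linalg.norm(ens.maps - ens.maps.mean(1, keepdims=True), axis=1)
               * np.linalg.norm(fc_g1 - fc_g1.mean()))
        )
        summary["structure_function"] = {
            "g1_similarity": float(obs),
            "sa_p": surr.sa_pvalue(obs, null, tail="right"),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "hashes": _hash_dir(out),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return summary
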