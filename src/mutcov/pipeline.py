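"""End-to-end orchestration: simulate -> rates -> bias -> M -> compare -> tensor.

A single YAML/JSON config with a global seed drives the run.  Each
enabled stage receives its own deterministically spawned random
substream, writes its artifacts under the output directory, and records
a manifest entry (stage, parameters, seed material and SHA-256 digests
of every file written), so a rerun with the same config and seed
reproduces every output byte for byte.

Significance conventions are centralized here: 95% bands for
permutation-null comparisons of variance terms, the 83% equal-tailed
credible-interval overlap rule for between-group contrasts, and
alpha = 0.05 for likelihood-ratio tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from . import compare as cmp
from . import ctmc, synthetic, tensor, varcomp

ALPHA = 0.05
NULL_BAND_LEVEL = 0.95
CI_OVERLAP_LEVEL = 0.83

STAGE_ORDER = ("simulate", "rates", "bias", "mmatrix", "compare", "tensor")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    seed: int
    output_dir: Path
    stages: dict[str, dict]
    input_phenotypes: Optional[Path] = None
    input_states: Optional[Path] = None

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, Any]) -> "PipelineConfig":
        if "seed" not in cfg:
            raise ValueError("config requires a 'seed'")
        stages = dict(cfg.get("stages", {}))
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for name, params in stages.items():
            if params is None:
                stages[name] = {}
        pheno = cfg.get("input_phenotypes")
        states = cfg.get("input_states")
        if pheno is not None and not Path(pheno).exists():
            raise ValueError(f"input_phenotypes does not exist: {pheno}")
        if states is not None and not Path(states).exists():
            raise ValueError(f"input_states does not exist: {states}")
        return cls(
            seed=int(cfg["seed"]),
            output_dir=Path(cfg.get("output_dir", "mutcov_out")),
            stages=stages,
            input_phenotypes=Path(pheno) if pheno else None,
            input_states=Path(states) if states else None,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_mapping(synthetic.load_config(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class RunResult:
    """Artifacts and manifest of a pipeline run."""

    output_dir: Path
    manifest: list[dict] = field(default_factory=list)
    artifacts: dict[str, Any] = field(default_factory=dict)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    idx = STAGE_ORDER.index(stage)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)))


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute enabled stages in dependency order.

    A stage failure aborts the run with the failing stage named; outputs
    written by earlier stages are retained.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    result = RunResult(output_dir=out)

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        params = config.stages[stage]
        rng = _stage_rng(config.seed, stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, params, rng, result)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            _write_manifest(result, out)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        result.manifest.append(
            {
                "stage": stage,
                "parameters": _jsonable(params),
                "seed": config.seed,
                "outputs": {str(p): _sha256(p) for p in outputs},
            }
        )
    _write_manifest(result, out)
    return result


def _write_manifest(result: RunResult, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))


# -- stages ------------------------------------------------------------------

def _stage_simulate(config, params, rng, result) -> list[Path]:
    out = config.output_dir
    designs = synthetic.default_designs(
        true_M=np.asarray(params["true_M"], float) if "true_M" in params else None,
        beta_ma=np.asarray(params["beta_ma"], float) if "beta_ma" in params else None,
        delta_background=(
            np.asarray(params["delta_background"], float)
            if "delta_background" in params
            else None
        ),
        n_ma_lines=tuple(params.get("n_ma_lines", (54, 62))),
        n_blocks=int(params.get("n_blocks", 16)),
        plates_per_line=int(params.get("plates_per_line", 2)),
    )
    table = synthetic.simulate_ma_experiment(designs, rng)
    pheno_path = out / "phenotypes.csv"
    synthetic.write_phenotype_table(table, pheno_path)
    result.artifacts["phenotypes"] = table
    written = [pheno_path]
    if "states" in params:
        sp = params["states"]
        design = synthetic.CTMCDesign(
            Q=ctmc.RateMatrix.from_rates(np.asarray(sp["rates"], float)),
            duration=float(sp.get("duration", 60.0)),
            frame_rate=float(sp.get("frame_rate", 4.0)),
            n_objects=int(sp.get("n_objects", 10)),
        )
        seqs = synthetic.simulate_plate(design, rng)
        states_path = out / "states.csv"
        synthetic.write_state_sequences(seqs, states_path)
        result.artifacts["states"] = seqs
        result.artifacts["states_frame_rate"] = design.frame_rate
        written.append(states_path)
    return written


def _stage_rates(config, params, rng, result) -> list[Path]:
    out = config.output_dir
    frame_rate = float(params.get("frame_rate", result.artifacts.get("states_frame_rate", 4.0)))
    if "states" in result.artifacts:
        seqs = result.artifacts["states"]
    else:
        src = config.input_states or (config.output_dir / "states.csv")
        seqs = synthetic.read_state_sequences(src, frame_rate=frame_rate)
    log_rates, fit = ctmc.summarize_plate_rates(seqs)
    row = {"plate_id": params.get("plate_id", "plate0")}
    row.update({f"ln_{t}": lr for t, lr in zip(ctmc.TRAITS, log_rates)})
    row["convergence_flag"] = int(fit.converged and not fit.flagged.any())
    rates_path = out / "rates.csv"
    pd.DataFrame([row]).to_csv(rates_path, index=False)
    result.artifacts["rates"] = row
    return [rates_path]


def _get_phenotypes(config, result) -> pd.DataFrame:
    if "phenotypes" in result.artifacts:
        return result.artifacts["phenotypes"]
    src = config.input_phenotypes or (config.output_dir / "phenotypes.csv")
    table = synthetic.read_phenotype_table(src)
    result.artifacts["phenotypes"] = table
    return table


def _stage_bias(config, params, rng, result) -> list[Path]:
    table = _get_phenotypes(config, result)
    report = varcomp.mutational_bias_analysis(table, alpha=float(params.get("alpha", ALPHA)))
    path = config.output_dir / "bias_table.csv"
    report.to_csv(path, index=False)
    result.artifacts["bias"] = report
    return [path]


def _stage_mmatrix(config, params, rng, result) -> list[Path]:
    table = _get_phenotypes(config, result)
    mcmc = {
        "n_iter": int(params.get("n_iter", varcomp.REDUCED_MCMC["n_iter"])),
        "burnin": int(params.get("burnin", varcomp.REDUCED_MCMC["burnin"])),
        "thin": int(params.get("thin", varcomp.REDUCED_MCMC["thin"])),
    }
    n_rand = int(params.get("n_rand", 0))
    null_mcmc = {
        "n_iter": int(params.get("null_n_iter", max(mcmc["n_iter"] // 10, 500))),
        "burnin": int(params.get("null_burnin", max(mcmc["burnin"] // 10, 100))),
        "thin": mcmc["thin"],
    }
    ma = table[table["ma_status"] == "MA"]
    written: list[Path] = []
    posteriors: dict[str, np.ndarray] = {}
    nulls: dict[str, np.ndarray] = {}
    for geno, sub in ma.groupby("genotype", sort=True):
        post = varcomp.fit_multivariate(sub, rng=rng, **mcmc)
        m_samples = varcomp.m_matrix(post)
        posteriors[geno] = m_samples
        mean_path = config.output_dir / f"M_{geno}.csv"
        pd.DataFrame(
            m_samples.mean(axis=0), index=post.traits, columns=post.traits
        ).to_csv(mean_path)
        written.append(mean_path)
        np.save(config.output_dir / f"M_{geno}_samples.npy", m_samples)
        written.append(config.output_dir / f"M_{geno}_samples.npy")
        if n_rand > 0:
            nulls[geno] = varcomp.randomized_null_matrices(
                sub, n_rand=n_rand, rng=rng, **null_mcmc
            )
            np.save(config.output_dir / f"M_{geno}_null.npy", nulls[geno])
            written.append(config.output_dir / f"M_{geno}_null.npy")
    result.artifacts["m_posteriors"] = posteriors
    result.artifacts["m_nulls"] = nulls
    return written


def _stage_compare(config, params, rng, result) -> list[Path]:
    posteriors = result.artifacts.get("m_posteriors")
    if not posteriors or len(posteriors) < 2:
        raise ValueError("compare needs M posteriors for two genotypes")
    labels = sorted(posteriors)
    a, b = labels[0], labels[1]
    mean_a = posteriors[a].mean(axis=0)
    mean_b = posteriors[b].mean(axis=0)
    eig_a = cmp.eigen_summary(mean_a)
    eig_b = cmp.eigen_summary(mean_b)
    null_angles = cmp.null_angle_samples(
        mean_a.shape[0], int(params.get("n_null_pairs", 1000)), rng
    )
    report: dict[str, Any] = {
        "genotypes": labels,
        "angle_mmax": cmp.angle(eig_a.mmax, eig_b.mmax),
        "null_angle_mean": null_angles.mean,
        "null_angle_ci95": null_angles.ci95,
        "trace": {
            a: float(np.trace(mean_a)),
            b: float(np.trace(mean_b)),
        },
        "trace_ci_compare": cmp.ci_compare(
            np.trace(posteriors[a], axis1=1, axis2=2),
            np.trace(posteriors[b], axis1=1, axis2=2),
            level=CI_OVERLAP_LEVEL,
        ),
        "lambda_max": {a: eig_a.lambda_max, b: eig_b.lambda_max},
        "pi": {
            f"{a}_along_{b}": _jsonable(vars(cmp.pi_posterior(posteriors[a], eig_b.mmax))),
            f"{b}_along_{a}": _jsonable(vars(cmp.pi_posterior(posteriors[b], eig_a.mmax))),
        },
    }
    # strip bulky sample arrays from the JSON report
    for v in report["pi"].values():
        v.pop("pi_samples", None)
        v.pop("pi0_samples", None)
    nulls = result.artifacts.get("m_nulls", {})
    sig = {}
    for lab, eig in ((a, eig_a), (b, eig_b)):
        if lab in nulls and len(nulls[lab]):
            rot = cmp.rotate_null_eigenvalues(nulls[lab], eig)
            band = rot["band95"]
            sig[lab] = {
                "lambda1": eig.lambda_max,
                "lambda1_null_band95": band[0].tolist(),
                "lambda1_significant": bool(eig.lambda_max > band[0][1]),
                "trace_null_band95": list(
                    cmp.equal_tailed_interval(
                        np.trace(nulls[lab], axis1=1, axis2=2), NULL_BAND_LEVEL
                    )
                ),
            }
            sig[lab]["trace_significant"] = bool(
                np.trace(posteriors[lab].mean(axis=0)) > sig[lab]["trace_null_band95"][1]
            )
    report["null_bands"] = sig
    path = config.output_dir / "compare.json"
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    result.artifacts["compare"] = report
    return [path]


def _stage_tensor(config, params, rng, result) -> list[Path]:
    posteriors = result.artifacts.get("m_posteriors")
    if not posteriors or len(posteriors) < 2:
        raise ValueError("tensor needs M posteriors for at least two matrices")
    mats = {lab: posteriors[lab].mean(axis=0) for lab in sorted(posteriors)}
    mset = tensor.MatrixSet(matrices=mats, posteriors=dict(posteriors))
    dec, coords = tensor.tensor_analysis(mset)
    post = tensor.tensor_posterior(mset, dec)
    report = {
        "labels": mset.labels,
        "alphas": dec.alphas.tolist(),
        "alpha_proportions": dec.alpha_proportions.tolist(),
        "coordinates": coords.tolist(),
        "e11": dec.e_vector(0, 0).tolist(),
        "e11_variance_proportion": float(
            dec.eigentensor_eigen[0].eigenvalues[0] ** 2
            / np.sum(dec.eigentensor_eigen[0].eigenvalues ** 2)
        ),
        "alpha_ci83": post["alpha_ci83"].tolist(),
        "alpha_ci95": post["alpha_ci95"].tolist(),
    }
    nulls = result.artifacts.get("m_nulls", {})
    if len(nulls) >= 2 and all(len(v) for v in nulls.values()):
        n_rep = min(v.shape[0] for v in nulls.values())
        null_sets = [
            {lab: nulls[lab][r] for lab in sorted(nulls)} for r in range(n_rep)
        ]
        nt = tensor.tensor_null(null_sets, dec)
        report["alpha_null_band95"] = nt["band95"].tolist()
        report["alpha1_significant"] = bool(dec.alphas[0] > nt["band95"][0][1])
    path = config.output_dir / "tensor.json"
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    result.artifacts["tensor"] = report
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rates": _stage_rates,
    "bias": _stage_bias,
    "mmatrix": _stage_mmatrix,
    "compare": _stage_compare,
    "tensor": _stage_tensor,
}


# -- report ------------------------------------------------------------------

def make_report(result: RunResult) -> str:
    """Human-readable summary mirroring the analysis's reporting shapes."""
    lines = ["# mutcov run report", ""]
    if "bias" in result.artifacts:
        lines += ["## Background effects and mutational bias", ""]
        lines.append(result.artifacts["bias"].round(4).to_string(index=False))
        lines.append("")
    if "m_posteriors" in result.artifacts:
        lines += ["## M matrices (posterior means)", ""]
        for lab, post in sorted(result.artifacts["m_posteriors"].items()):
            mean = post.mean(axis=0)
            lines.append(f"### {lab}")
            lines.append(f"trace = {np.trace(mean):.4f}")
            lines.append(pd.DataFrame(mean).round(4).to_string())
            lines.append("")
    if "compare" in result.artifacts:
        rep = result.artifacts["compare"]
        lines += ["## M matrix comparison", ""]
        lines.append(f"angle(mmax, mmax) = {rep['angle_mmax']:.2f} deg "
                     f"(null mean {rep['null_angle_mean']:.2f})")
        verdict = rep["trace_ci_compare"]["different"]
        lines.append(
            f"trace different at {int(CI_OVERLAP_LEVEL*100)}% CI overlap rule: "
            + ("yes *" if verdict else "no")
        )
        for lab, s in rep.get("null_bands", {}).items():
            star = " *" if s["lambda1_significant"] else ""
            lines.append(
                f"{lab}: lambda1 = {s['lambda1']:.4f}, null 95% band "
                f"[{s['lambda1_null_band95'][0]:.4f}, {s['lambda1_null_band95'][1]:.4f}]{star}"
            )
        lines.append("")
    if "tensor" in result.artifacts:
        rep = result.artifacts["tensor"]
        lines += ["## Eigentensor analysis", ""]
        props = rep["alpha_proportions"]
        lines.append(
            "alpha proportions: "
            + ", ".join(f"E{i+1}={p:.2%}" for i, p in enumerate(props[:3]))
        )
        if "alpha1_significant" in rep:
            lines.append(
                "E1 above null band" + (" *" if rep["alpha1_significant"] else ": no")
            )
        lines.append("")
    return "\n".join(lines)
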