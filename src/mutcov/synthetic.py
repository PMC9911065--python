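"""Synthetic data with the statistical structure the analysis assumes.

Two generators are provided:

* movement-state sequences from a known generator matrix ``Q``, by exact
  continuous-time simulation (exponential holding times and embedded-chain
  jumps) sampled at frame times — the raw input of the rate-estimation
  stage;
* plate-level phenotype tables of the six log transition rates, built by
  inverting the multivariate mixed model fitted downstream: each plate row
  is group mean + covariate effects + line effect + block effect +
  residual, with line effects drawn from N(0, 2*M) (inbred, homozygous
  lines carry twice the mutational covariance), block effects from
  N(0, B) and residuals from N(0, E).

A four-group mutation-accumulation layout (two founder genotypes, each
with an ancestor and a set of MA lines, sharing assay blocks) mirrors the
design the bias analysis expects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ctmc import RateMatrix, StateSequence, STATES, STATE_INDEX, TRAITS

TRAIT_COLS: tuple[str, ...] = tuple(f"ln_{t}" for t in TRAITS)
COVARIATE_COLS: tuple[str, ...] = ("temperature", "humidity", "log_density")
GROUPS: tuple[str, ...] = ("ancestor", "MA")

_PSD_TOL = -1e-10


def _check_psd(a: np.ndarray, name: str, strict: bool = False) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (6, 6):
        raise ValueError(f"{name} must be 6x6")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(a)
    if strict and w.min() <= 0:
        raise ValueError(f"{name} must be positive definite")
    if w.min() < _PSD_TOL:
        raise ValueError(f"{name} must be positive semi-definite")
    return a


@dataclass(frozen=True)
class CTMCDesign:
    """Parameters of a simulated tracking movie."""

    Q: RateMatrix
    duration: float  # seconds
    frame_rate: float = 4.0  # frames per second
    n_objects: int = 1
    #: optional initial state distribution over (S, F, B); uniform if None
    p0: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if self.p0 is not None:
            p0 = np.asarray(self.p0, dtype=float)
            if p0.shape != (3,) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
                raise ValueError("p0 must be a probability vector of length 3")
            object.__setattr__(self, "p0", p0)


def simulate_state_sequence(
    design: CTMCDesign,
    rng: np.random.Generator,
    object_id: str = "0",
    initial_state: Optional[str] = None,
) -> StateSequence:
    """Exact CTMC simulation sampled at frame times.

    Holding times are exponential with rate -q_ii; jumps follow the
    embedded chain q_ij / (-q_ii).  The continuous path is then read out
    at times 0, 1/frame_rate, 2/frame_rate, ... up to ``duration``.
    """
    Q = design.Q.q
    dt = 1.0 / design.frame_rate
    n_frames = int(np.floor(design.duration * design.frame_rate)) + 1
    if initial_state is not None:
        state = STATE_INDEX[initial_state]
    elif design.p0 is not None:
        state = int(rng.choice(3, p=design.p0))
    else:
        state = int(rng.integers(3))

    out = np.empty(n_frames, dtype="U1")
    t = 0.0
    frame = 0
    while frame < n_frames:
        exit_rate = -Q[state, state]
        if exit_rate <= 0:
            out[frame:] = STATES[state]
            break
        t_next = t + rng.exponential(1.0 / exit_rate)
        # emit frames falling inside the current holding interval
        last = min(n_frames - 1, int(np.floor(t_next / dt)))
        if t_next / dt > frame:  # at least one frame before the jump
            out[frame : last + 1] = STATES[state]
            frame = last + 1
        probs = Q[state].copy()
        probs[state] = 0.0
        state = int(rng.choice(3, p=probs / exit_rate))
        t = t_next
    return StateSequence(states=out, dt=dt, object_id=object_id)


def simulate_plate(design: CTMCDesign, rng: np.random.Generator) -> list[StateSequence]:
    """Simulate ``design.n_objects`` independent tracked objects."""
    return [
        simulate_state_sequence(design, rng, object_id=str(k))
        for k in range(design.n_objects)
    ]


# -- phenotype tables --------------------------------------------------------

#: Default covariate distributions: ambient temperature (deg C), relative
#: humidity (%) and natural-log worm density per plate.
DEFAULT_COVARIATE_DISTS: dict[str, tuple[float, float]] = {
    "temperature": (20.0, 0.5),
    "humidity": (50.0, 5.0),
    "log_density": (6.9, 0.3),
}


@dataclass(frozen=True)
class SimulationDesign:
    """Generating parameters of one group of inbred lines.

    ``true_M`` is the mutational covariance matrix; line effects are drawn
    with covariance 2*true_M because fixed mutations in fully selfed lines
    are homozygous.  ``group_means`` maps group labels (e.g. "N2:MA") to
    6-vectors of mean log rates, which is where the fixed-effect structure
    of the bias model (founder mean, background difference, MA shift and
    their interaction) lives as generating parameters.
    """

    n_lines_per_group: int
    n_blocks: int
    plates_per_line: int
    true_M: np.ndarray
    true_block_cov: np.ndarray
    true_residual_cov: np.ndarray
    covariate_effects: np.ndarray  # 6 traits x 3 covariates
    group_means: Mapping[str, np.ndarray]
    seed: Optional[int] = None
    covariate_dists: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DISTS)
    )

    def __post_init__(self) -> None:
        for name in ("n_lines_per_group", "n_blocks", "plates_per_line"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.plates_per_line > self.n_blocks:
            raise ValueError("plates_per_line cannot exceed n_blocks")
        object.__setattr__(self, "true_M", _check_psd(self.true_M, "true_M"))
        object.__setattr__(
            self, "true_block_cov", _check_psd(self.true_block_cov, "true_block_cov")
        )
        object.__setattr__(
            self,
            "true_residual_cov",
            _check_psd(self.true_residual_cov, "true_residual_cov", strict=True),
        )
        ce = np.asarray(self.covariate_effects, dtype=float)
        if ce.shape != (6, 3):
            raise ValueError("covariate_effects must be 6x3")
        object.__setattr__(self, "covariate_effects", ce)
        gm = {k: np.asarray(v, dtype=float) for k, v in self.group_means.items()}
        for k, v in gm.items():
            if v.shape != (6,):
                raise ValueError(f"group mean {k!r} must be a 6-vector")
        object.__setattr__(self, "group_means", gm)


def _draw_psd(cov: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Multivariate normal draws tolerant of semi-definite covariance."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    A = v * np.sqrt(w)
    return rng.standard_normal((size, cov.shape[0])) @ A.T


def _block_assignment(
    n_lines: int, n_blocks: int, plates_per_line: int, rng: np.random.Generator
) -> list[np.ndarray]:
    return [
        rng.choice(n_blocks, size=plates_per_line, replace=False)
        for _ in range(n_lines)
    ]


def simulate_phenotypes(
    design: SimulationDesign,
    rng: np.random.Generator,
    group: Optional[str] = None,
    block_effects: Optional[np.ndarray] = None,
    line_prefix: str = "L",
    return_latents: bool = False,
) -> pd.DataFrame:
    """Simulate a plate-level phenotype table for one group of lines.

    Each line's random effect is drawn once and shared by all its plates;
    every plate additionally receives its block's effect, covariate
    contributions and a multivariate residual.  With ``return_latents``
    the drawn line and block effects are returned alongside the table
    (useful as a ground-truth oracle).
    """
    if group is None:
        group = next(iter(design.group_means))
    if group not in design.group_means:
        raise ValueError(f"unknown group {group!r}")
    mean = design.group_means[group]
    genotype, _, ma_status = group.partition(":")
    ma_status = ma_status or "MA"

    n_lines = design.n_lines_per_group
    line_eff = _draw_psd(2.0 * design.true_M, n_lines, rng)
    if block_effects is None:
        block_effects = _draw_psd(design.true_block_cov, design.n_blocks, rng)
    assignment = _block_assignment(
        n_lines, design.n_blocks, design.plates_per_line, rng
    )

    n_rows = n_lines * design.plates_per_line
    residuals = _draw_psd(design.true_residual_cov, n_rows, rng)
    rows = []
    r = 0
    for li in range(n_lines):
        for b in assignment[li]:
            covs = {
                name: rng.normal(*design.covariate_dists[name])
                for name in COVARIATE_COLS
            }
            x = np.array([covs[c] - design.covariate_dists[c][0] for c in COVARIATE_COLS])
            y = (
                mean
                + design.covariate_effects @ x
                + line_eff[li]
                + block_effects[b]
                + residuals[r]
            )
            r += 1
            rows.append(
                {
                    "line_id": f"{line_prefix}{li:03d}",
                    "block_id": f"B{b:02d}",
                    "genotype": genotype,
                    "ma_status": ma_status,
                    **covs,
                    **dict(zip(TRAIT_COLS, y)),
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "plate_id", [f"{line_prefix}P{i:04d}" for i in range(len(df))])
    if return_latents:
        return df, {"line_effects": line_eff, "block_effects": block_effects}
    return df


def simulate_ma_experiment(
    designs: Mapping[str, SimulationDesign],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate the four-group MA assay in a single table.

    ``designs`` maps group labels "<genotype>:<ancestor|MA>" for two
    genotype backgrounds to their generating designs.  Assay blocks are
    shared across groups: block effects are drawn once from the first
    design's block covariance, so lines of different groups measured in
    the same block share its effect (as in a thaw-block design).
    """
    labels = list(designs)
    genotypes = sorted({lab.partition(":")[0] for lab in labels})
    if len(genotypes) != 2:
        raise ValueError(f"expected two genotype backgrounds, got {genotypes}")
    required = {f"{g}:{s}" for g in genotypes for s in GROUPS}
    missing = required - set(labels)
    if missing:
        raise ValueError(f"missing group(s): {sorted(missing)}")

    first = designs[labels[0]]
    n_blocks = first.n_blocks
    for lab, d in designs.items():
        if d.n_blocks != n_blocks:
            raise ValueError("all groups must share the same number of blocks")
    block_effects = _draw_psd(first.true_block_cov, n_blocks, rng)

    tables = []
    for lab in sorted(required):
        tables.append(
            simulate_phenotypes(
                designs[lab],
                rng,
                group=lab,
                block_effects=block_effects,
                line_prefix=lab.replace(":", "_") + "_",
            )
        )
    df = pd.concat(tables, ignore_index=True)
    df["plate_id"] = [f"P{i:04d}" for i in range(len(df))]
    return df


def ma_group_means(
    alpha: np.ndarray,
    beta_ma: np.ndarray,
    delta_background: np.ndarray,
    eta_interaction: np.ndarray,
    backgrounds: tuple[str, str] = ("N2", "PB306"),
) -> dict[str, np.ndarray]:
    """Group means from the bias-model fixed effects.

    alpha: founder mean of the reference background; beta_ma: MA shift in
    the reference background; delta_background: mean difference of the
    second background; eta_interaction: extra MA shift in the second
    background.
    """
    a = np.asarray(alpha, float)
    b = np.asarray(beta_ma, float)
    d = np.asarray(delta_background, float)
    e = np.asarray(eta_interaction, float)
    ref, other = backgrounds
    return {
        f"{ref}:ancestor": a,
        f"{ref}:MA": a + b,
        f"{other}:ancestor": a + d,
        f"{other}:MA": a + d + b + e,
    }


# -- realistic defaults ------------------------------------------------------

def default_true_m(scale: float = 0.15, corr: float = 0.3) -> np.ndarray:
    """A plausible mutational covariance: equal variances, mild positive
    correlation between rates sharing a source state."""
    m = np.eye(6) * scale
    # pairs sharing a source state: (SF,SB), (FS,FB), (BS,BF)
    for i in (0, 2, 4):
        m[i, i + 1] = m[i + 1, i] = corr * scale
    return m


def default_designs(
    true_M: Optional[np.ndarray] = None,
    beta_ma: Optional[np.ndarray] = None,
    delta_background: Optional[np.ndarray] = None,
    eta_interaction: Optional[np.ndarray] = None,
    n_ma_lines: tuple[int, int] = (54, 62),
    n_blocks: int = 16,
    plates_per_line: int = 2,
) -> dict[str, SimulationDesign]:
    """Study-condition defaults for the four-group MA experiment.

    54 and 62 MA lines for the two backgrounds, 16 assay blocks, most
    lines measured on two plates in separate blocks, ancestors replicated
    across all blocks.
    """
    true_M = default_true_m() if true_M is None else np.asarray(true_M, float)
    zeros = np.zeros(6)
    means = ma_group_means(
        alpha=zeros,
        beta_ma=zeros if beta_ma is None else beta_ma,
        delta_background=zeros if delta_background is None else delta_background,
        eta_interaction=zeros if eta_interaction is None else eta_interaction,
    )
    block_cov = np.eye(6) * 0.05
    resid_cov = np.eye(6) * 0.2
    cov_eff = np.zeros((6, 3))
    cov_eff[:, 0] = 0.05  # modest temperature sensitivity on all rates

    def make(n_lines: int, plates: int) -> SimulationDesign:
        return SimulationDesign(
            n_lines_per_group=n_lines,
            n_blocks=n_blocks,
            plates_per_line=plates,
            true_M=true_M,
            true_block_cov=block_cov,
            true_residual_cov=resid_cov,
            covariate_effects=cov_eff,
            group_means=means,
        )

    ancestor = make(1, n_blocks)  # founders present in every block
    return {
        "N2:ancestor": ancestor,
        "N2:MA": make(n_ma_lines[0], plates_per_line),
        "PB306:ancestor": ancestor,
        "PB306:MA": make(n_ma_lines[1], plates_per_line),
    }


def single_group_design(
    n_lines: int = 100,
    n_blocks: int = 10,
    plates_per_line: int = 2,
    true_M: Optional[np.ndarray] = None,
    block_scale: float = 0.05,
    residual_scale: float = 0.2,
    group: str = "N2:MA",
) -> SimulationDesign:
    """One-group design for covariance-recovery studies."""
    true_M = default_true_m() if true_M is None else np.asarray(true_M, float)
    cov_eff = np.zeros((6, 3))
    cov_eff[:, 0] = 0.05
    return SimulationDesign(
        n_lines_per_group=n_lines,
        n_blocks=n_blocks,
        plates_per_line=plates_per_line,
        true_M=true_M,
        true_block_cov=np.eye(6) * block_scale,
        true_residual_cov=np.eye(6) * residual_scale,
        covariate_effects=cov_eff,
        group_means={group: np.zeros(6)},
    )


# -- I/O ---------------------------------------------------------------------

def write_phenotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_state_sequences(sequences: Iterable[StateSequence], path: str | Path) -> None:
    """CSV with columns object_id, frame_index, state (one row per frame)."""
    frames = []
    for seq in sequences:
        frames.append(
            pd.DataFrame(
                {
                    "object_id": seq.object_id,
                    "frame_index": np.arange(len(seq)),
                    "state": seq.states,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_state_sequences(path: str | Path, frame_rate: float = 4.0) -> list[StateSequence]:
    df = pd.read_csv(path)
    dt = 1.0 / frame_rate
    return [
        StateSequence(states=g["state"].to_numpy(), dt=dt, object_id=str(oid))
        for oid, g in df.groupby("object_id", sort=True)
    ]


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON design config; a seed entry is mandatory."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict) or "seed" not in cfg:
        raise ValueError("config must be a mapping with a 'seed' entry")
    return cfg


def design_from_config(cfg: Mapping) -> SimulationDesign:
    """Build a SimulationDesign from a plain mapping (parsed YAML/JSON)."""
    return SimulationDesign(
        n_lines_per_group=int(cfg["n_lines_per_group"]),
        n_blocks=int(cfg["n_blocks"]),
        plates_per_line=int(cfg["plates_per_line"]),
        true_M=np.asarray(cfg["true_M"], float),
        true_block_cov=np.asarray(cfg["true_block_cov"], float),
        true_residual_cov=np.asarray(cfg["true_residual_cov"], float),
        covariate_effects=np.asarray(cfg["covariate_effects"], float),
        group_means={k: np.asarray(v, float) for k, v in cfg["group_means"].items()},
        seed=cfg.get("seed"),
    )
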