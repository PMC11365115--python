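"""Run configuration, pipelines, serialization and fixture generation.

Configs are plain YAML mappings mirroring :class:`RunConfig`; every output
file embeds the SHA-256 hash of the canonical config so results can be
traced to their inputs.  All pipelines are deterministic: rerunning a
config byte-reproduces the primary CSV/JSON outputs.  The random seed is
accepted and recorded for provenance even though no stage draws random
numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import LineTensions, SystemSpec, WallModel, system_from_d_ratio
from .saddle import classify_region, find_saddle, scan_phase_diagram
from .scft import ChainModel, FieldState, Grid
from . import membrane as mem

__all__ = ["RunConfig", "run_pipeline", "generate_fixtures", "config_hash"]

log = logging.getLogger("rimpore")

MODES = ("saddle", "phase-diagram", "bilayer", "kappa", "line-tensions", "full-pipeline")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "saddle"
    # phenomenological model
    lambda_e: float = 0.9
    lambda_p: float = 0.5
    d_over_rh0: float = 0.0
    wall_c_h: float = 2.0
    wall_c_p: float = 2.0
    grid: list = field(default_factory=lambda: [0.5, 1.2, 5, 0.4, 1.2, 5])
    # molecular model
    f: float = 0.8
    chiN: float = 30.0
    alpha: float = 0.1
    contour_step: float = 0.005
    two_d_over_D: float = 2.75
    # numerics / bookkeeping
    tolerance: float = 1e-6
    outdir: str = "rimpore-out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def system(self) -> SystemSpec:
        return system_from_d_ratio(
            self.d_over_rh0, WallModel(c_h=self.wall_c_h, c_p=self.wall_c_p)
        )

    @property
    def chain(self) -> ChainModel:
        return ChainModel(
            f=self.f, chiN=self.chiN, alpha=self.alpha, contour_step=self.contour_step
        )


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific content (output location excluded)."""
    payload = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = dict(payload)
    payload["config_hash"] = config_hash(config)
    payload["seed"] = config.seed
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def _write_csv(path: Path, table: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash(config)} seed={config.seed}\n")
        table.to_csv(fh, index=False, float_format="%.12g")


def _write_fields_h5(path: Path, state: FieldState, config: RunConfig) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["config_hash"] = config_hash(config)
        h5.attrs["f"] = state.chain.f
        h5.attrs["chiN"] = state.chain.chiN
        h5.attrs["ensemble"] = state.ensemble
        h5.create_dataset("grid/lengths", data=np.asarray(state.grid.lengths))
        h5.create_dataset("grid/shape", data=np.asarray(state.grid.shape))
        for name in ("w_A", "w_B", "phi_A", "phi_B", "phi_S", "xi"):
            arr = getattr(state, name)
            if arr is not None:
                h5.create_dataset(name, data=arr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute one mode and write its artifacts; returns the summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log.info("mode=%s hash=%s", config.mode, config_hash(config))
    summary: dict = {"mode": config.mode}

    if config.mode == "saddle":
        lt = LineTensions(config.lambda_e, config.lambda_p)
        system = config.system
        res = find_saddle(lt, system)
        summary["region"] = classify_region(lt, system).value
        if res is None:
            summary["saddle"] = None
        else:
            g = res.geometry
            summary["saddle"] = {
                "Rh": g.Rh, "Re": g.Re, "Rp": g.Rp, "a": g.a,
                "bow_e": g.bow_e, "bow_p": g.bow_p,
                "Sigma": res.Sigma, "F": res.F, "dF": res.dF,
                "area_fraction": res.pore_area_fraction,
                "hessian_eigenvalues": list(res.hessian_eigenvalues),
                "hessian_eigenvalues_fixed_Rh": list(res.hessian_eigenvalues_fixed_Rh),
                "grad_norm": res.grad_norm,
            }
        _write_json(out / "saddle.json", summary, config)

    elif config.mode == "phase-diagram":
        le0, le1, n_e, lp0, lp1, n_p = config.grid
        table = scan_phase_diagram(
            np.linspace(le0, le1, int(n_e)),
            np.linspace(lp0, lp1, int(n_p)),
            config.system,
        )
        _write_csv(out / "phase_diagram.csv", table, config)
        summary["n_cells"] = len(table)
        summary["n_converged"] = int((table["status"] == "converged").sum())
        _write_json(out / "phase_diagram.json", summary, config)

    elif config.mode == "bilayer":
        flat = mem.tensionless_bilayer(config.chain, tol=config.tolerance)
        summary.update(
            D=flat.D, mu_star=flat.mu_star, Sigma=flat.Sigma,
            area_per_lipid=flat.area_per_lipid,
        )
        _write_json(out / "bilayer.json", summary, config)
        _write_fields_h5(out / "bilayer_fields.h5", flat.state, config)
        # convergence log of a fresh solve at the tensionless point
        from .scft import FieldState, solve_scft
        import math as _math

        st = FieldState(
            grid=flat.grid, chain=config.chain,
            w_A=flat.state.w_A.copy(), w_B=flat.state.w_B.copy(),
            ensemble="grand", z_l=_math.exp(flat.mu_star), z_s=1.0,
        )
        sol = solve_scft(st, tol=config.tolerance, max_iter=2000,
                         raise_on_failure=False)
        log_table = pd.DataFrame(
            {
                "iteration": np.arange(len(sol.residual_history)),
                "residual": sol.residual_history,
            }
        )
        log_table["free_energy"] = np.nan
        log_table.loc[len(log_table) - 1, "free_energy"] = sol.free_energy
        _write_csv(out / "bilayer_convergence.csv", log_table, config)

    elif config.mode == "kappa":
        flat = mem.tensionless_bilayer(config.chain, tol=config.tolerance)
        kappa, fit = mem.bending_modulus(config.chain, flat, return_fit=True)
        summary.update(kappa=kappa, D=flat.D, fit_r2=fit["r2"])
        _write_json(out / "kappa.json", summary, config)

    elif config.mode == "line-tensions":
        flat = mem.tensionless_bilayer(config.chain, tol=config.tolerance)
        d = config.two_d_over_D * flat.D / 2.0
        lt = mem.line_tension_ratios(config.chain, d, flat=flat)
        summary.update(lt)
        _write_json(out / "line_tensions.json", summary, config)

    elif config.mode == "full-pipeline":
        flat = mem.tensionless_bilayer(config.chain, tol=config.tolerance)
        d = config.two_d_over_D * flat.D / 2.0
        lt = mem.line_tension_ratios(config.chain, d, flat=flat)
        ratios = LineTensions(lt["lambda_e_over_h"], lt["lambda_p_over_h"])
        system = config.system
        res = find_saddle(ratios, system)
        summary.update(
            D=flat.D,
            lambda_e_over_h=lt["lambda_e_over_h"],
            lambda_p_over_h=lt["lambda_p_over_h"],
            region=classify_region(ratios, system).value,
            area_fraction=None if res is None else res.pore_area_fraction,
        )
        _write_json(out / "pipeline.json", summary, config)

    summary["wall_time_s"] = time.time() - t0
    log.info("done in %.1fs", summary["wall_time_s"])
    return summary


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

TENSION_SETS = [
    {"lambda_e": 0.4, "lambda_p": 0.4, "expected_region": "UNZIP_UNSTABLE"},
    {"lambda_e": 1.5, "lambda_p": 0.3, "expected_region": "EDGE_UNBALANCED"},
    {"lambda_e": 0.3, "lambda_p": 1.5, "expected_region": "DETACH_PREFERRED"},
    {"lambda_e": 0.9, "lambda_p": 0.5, "expected_region": "CRITICAL_RECESSED"},
    {"lambda_e": 1.2, "lambda_p": 0.9, "expected_region": "CRITICAL_PROTRUDING_OUT"},
    {"lambda_e": 0.55, "lambda_p": 1.5, "expected_region": "CRITICAL_PROTRUDING_IN"},
    {"lambda_e": 1.0, "lambda_p": 0.6, "expected_region": "CRITICAL_PROTRUDING_OUT"},
]


def scft_seed_state(kind: str, chain: ChainModel | None = None, d: float = 1.5) -> FieldState:
    """Deterministic seed field states (bilayer, edge, junction, wall)."""
    chain = chain or ChainModel()
    if kind == "bilayer":
        n = int(round(mem.BOX_1D / mem.GRID_SPACING))
        grid = Grid(lengths=(mem.BOX_1D,), shape=(n,), bc=("neumann",))
        x = grid.axis_coords(0)
        dist = np.abs(x - mem.BOX_1D / 2)
    else:
        key = {"edge": "e", "junction": "h", "wall": "p"}[kind]
        nx, ny = (int(round(L / mem.GRID_SPACING)) for L in mem.BOX_2D)
        grid = Grid(lengths=mem.BOX_2D, shape=(nx, ny), bc=("neumann", "neumann"))
        dist = mem._skeleton_distance(key, grid, d)
    core = 0.96 * 0.5 * (1 - np.tanh((dist - 0.55) / 0.12))
    return FieldState(
        grid=grid, chain=chain,
        w_A=chain.chiN * core, w_B=chain.chiN * (1 - core),
        ensemble="canonical", phi_lipid_bar=0.18,
    )


def generate_fixtures(kind: str, size: int = 5, outdir: str | Path = "fixtures") -> Path:
    """Write small deterministic input sets used by tests and examples."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "tension-sets":
        path = out / "tension_sets.json"
        path.write_text(json.dumps(TENSION_SETS, indent=2) + "\n")
        return path
    if kind == "scft-seeds":
        path = out / "scft_seeds.json"
        descr = {
            name: {"kind": name, "f": 0.8, "chiN": 30.0, "alpha": 0.1}
            for name in ("bilayer", "edge", "junction", "wall")
        }
        path.write_text(json.dumps(descr, indent=2) + "\n")
        return path
    if kind == "phase-grid":
        path = out / f"phase_grid_{size}.csv"
        les = np.linspace(0.5, 1.2, size)
        lps = np.linspace(0.4, 1.2, size)
        rows = [
            {"lambda_e": float(le), "lambda_p": float(lp)} for le in les for lp in lps
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path
    raise ValueError(f"unknown fixture kind {kind!r}")
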