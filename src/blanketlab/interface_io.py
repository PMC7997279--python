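"""System/report JSON formats, full-analysis orchestration and the CLI.

System files are JSON, schema version 1, with matrices inline
(row-major nested lists; the dense dimensions used here make binary
formats unnecessary).  Two forms are accepted:

* ``{"partition": {...}, "M": [[...]], "Gamma": [[...]]}`` — the drift
  form; the solenoidal matrix and stationary precision are derived;
* ``{"partition": {...}, "U": [[...]], "R": [[...]], "Gamma": [[...]]}``
  — the potential form; the drift is assembled as ``M = -(Gamma+R)U``.

A ``convention`` field is fixed to ``"noise_cov=2*Gamma"`` so files are
self-describing about the noise normalisation.  Reports are JSON too
and never mix logs and data; logging goes to standard error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .errors import (
    AsymmetryError,
    DimensionError,
    InvariantError,
    MissingMatrixError,
    NonErgodicError,
    NotSPDError,
    SchemaError,
)
from .blanket_conditions import check_condition, verify_chain_implication
from .flow_identities import MARGINAL_FAMILIES, identity_residuals
from .lemma_analysis import dpi_check, kl_supremum_probe, lemma_feasibility
from .generalised_coordinates import lift_generalised
from .linsys_core import (
    CoordinatePartition,
    LinearOUSystem,
    TOL_STRUCTURAL,
    assemble_from_potential,
    is_antisymmetric,
    is_block_diagonal,
    is_hurwitz,
    is_spd,
    specnorm,
)
from .simulate_validate import simulate_em, validate_empirical
from .synthetic_systems import OBSERVATIONS, generate_counterexample

logger = logging.getLogger("blanketlab")

SCHEMA_VERSION = 1
CONVENTION = "noise_cov=2*Gamma"
_ALLOWED_KEYS = {"schema_version", "convention", "partition", "M", "Gamma", "U", "R",
                 "comment"}


@dataclass
class SystemData:
    """A loaded system file: the OU system plus any matrices it carried."""

    system: LinearOUSystem
    U: np.ndarray | None = None
    R: np.ndarray | None = None
    source_form: str = "drift"   # "drift" (M given) | "potential" (U, R given)

    @property
    def partition(self) -> CoordinatePartition:
        return self.system.partition


def system_to_dict(system: LinearOUSystem, include_potential: bool = False) -> dict:
    out = {
        "schema_version": SCHEMA_VERSION,
        "convention": CONVENTION,
        "partition": system.partition.to_dict(),
        "M": system.M.tolist(),
        "Gamma": system.Gamma.tolist(),
    }
    if include_potential:
        out["U"] = system.U.tolist()
        out["R"] = system.R.tolist()
    return out


def write_system(path: str | Path, system: LinearOUSystem,
                 include_potential: bool = False) -> None:
    Path(path).write_text(json.dumps(system_to_dict(system, include_potential), indent=1))


def read_system(path: str | Path) -> SystemData:
    """Load and validate a system JSON file.

    Validation order: schema (unknown fields, version, partition keys),
    dimensions, then structural invariants — each failure names the
    offending field.
    """
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError("top level must be a JSON object")
    unknown = set(data) - _ALLOWED_KEYS
    if unknown:
        raise SchemaError(f"unknown fields: {sorted(unknown)}")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version!r}")
    if data.get("convention", CONVENTION) != CONVENTION:
        raise SchemaError(f"unsupported convention {data.get('convention')!r}")
    part_raw = data.get("partition")
    if not isinstance(part_raw, dict):
        raise SchemaError("missing or malformed 'partition'")
    if set(part_raw) != {"psi", "s", "a", "lambda"}:
        raise SchemaError(
            f"partition must have exactly the keys psi, s, a, lambda; got {sorted(part_raw)}"
        )
    partition = CoordinatePartition.from_dict(part_raw)
    d = partition.d

    def mat(name: str) -> np.ndarray | None:
        if name not in data:
            return None
        arr = np.asarray(data[name], dtype=float)
        if arr.shape != (d, d):
            raise DimensionError(
                f"{name} has shape {arr.shape}, but the partition implies {d}x{d}"
            )
        return arr

    Gamma = mat("Gamma")
    if Gamma is None:
        raise MissingMatrixError("system file must carry Gamma")
    if not is_spd(Gamma):
        raise InvariantError("Gamma is not symmetric positive definite")
    if not is_block_diagonal(Gamma, partition):
        raise InvariantError("Gamma is not block-diagonal over the partition")

    M, U, R = mat("M"), mat("U"), mat("R")
    if M is not None:
        if not is_hurwitz(M):
            raise InvariantError("M is not Hurwitz")
        system = LinearOUSystem(partition=partition, M=M, Gamma=Gamma)
        return SystemData(system=system, U=U, R=R, source_form="drift")
    if U is not None and R is not None:
        if not is_spd(U):
            raise InvariantError("U is not symmetric positive definite")
        if not is_antisymmetric(R):
            raise InvariantError("R is not antisymmetric")
        try:
            system = assemble_from_potential(U, R, Gamma, partition)
        except (NotSPDError, AsymmetryError, NonErgodicError) as exc:
            raise InvariantError(str(exc)) from exc
        return SystemData(system=system, U=U, R=R, source_form="potential")
    raise MissingMatrixError("system file must carry either M or both U and R")


def _input_hash(system: LinearOUSystem) -> str:
    payload = json.dumps(system_to_dict(system), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_full_analysis(source: str | Path | LinearOUSystem, tol: float = TOL_STRUCTURAL,
                      lift_order: int | None = None, probe_c: float = 10.0,
                      simulate: bool = False, sim_steps: int = 200_000,
                      sim_dt: float = 0.01, seed: int = 0) -> dict:
    """Run the full analysis pipeline on one system and return a JSON-able report.

    Stages: blanket conditions -> chain check -> flow identities ->
    free-energy feasibility (per applicable family, with a KL probe on
    feasible ones) -> information inequality -> optional lift and
    simulation cross-check.  The report states which structural
    phenomena this particular system witnesses.
    """
    if isinstance(source, LinearOUSystem):
        system = source
    else:
        system = read_system(source).system
    logger.info("analysis start: d=%d seed=%d", system.d, seed)
    report: dict = {
        "tool": {"name": "blanketlab", "version": __version__},
        "input_hash": _input_hash(system),
        "seed": seed,
        "tol": tol,
    }
    conds = {cid: check_condition(system, cid, tol) for cid in (1, 2, 3)}
    report["conditions"] = {str(cid): rep.to_dict() for cid, rep in conds.items()}
    report["chain"] = verify_chain_implication(system).to_dict()
    idrep = identity_residuals(system, tol)
    report["identities"] = idrep.to_dict()

    lemma: dict = {}
    for family in MARGINAL_FAMILIES:
        feas = lemma_feasibility(system, family)
        entry = feas.to_dict()
        if feas.status == "ok" and feas.feasible:
            probe = kl_supremum_probe(system, feas, c=probe_c)
            entry["probe"] = probe.to_dict()
        lemma[family] = entry
    report["lemma"] = lemma
    report["information"] = dpi_check(system).to_dict()

    c1, c2 = conds[1].satisfied, conds[2].satisfied
    feas_diag = lemma["diagonal"]
    report["witnesses"] = {
        "conditions_disagree_forward": bool(c1 and conds[2].violated),
        "conditions_disagree_reverse": bool(c2 and conds[1].violated),
        "partial_gradient_reduction_fails": bool(
            c1 and c2 and (idrep.fails("diagonal") or idrep.fails("cross"))
        ),
        "lemma_infeasible_gaussian_linear": bool(
            feas_diag.get("status") == "ok" and feas_diag.get("feasible") is False
        ),
        "kl_unbounded_at_vanishing_gradients": bool(
            feas_diag.get("probe", {}).get("kl", 0.0) > probe_c
            and feas_diag.get("probe", {}).get("gradients_vanish", False)
            and feas_diag.get("probe", {}).get("gain_mismatch", 0.0) > 0
        ),
    }

    if lift_order is not None:
        lifted = lift_generalised(system, lift_order)
        lifted_id = identity_residuals(lifted.system, tol)
        report["lift"] = {
            "order": lift_order,
            "conditions": {
                str(cid): check_condition(lifted.system, cid, tol).to_dict()
                for cid in (1, 2, 3)
            },
            "identities": lifted_id.to_dict(),
        }
    if simulate:
        summary = simulate_em(system, n_steps=sim_steps, dt=sim_dt, seed=seed)
        z = validate_empirical(summary, system.stationary)
        report["simulation"] = {
            "n_steps": sim_steps, "dt": sim_dt, "seed": seed,
            "min_ess": summary.min_ess,
            "max_abs_z": z.max_abs_z, "passed": z.passed,
        }
    logger.info("analysis done: hash=%s", report["input_hash"])
    return report


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

import click  # noqa: E402  (kept after the library surface on purpose)


def _setup_logging(level: str) -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper()),
                        format="%(levelname)s %(name)s: %(message)s")


def _dump(data: dict, out: str | None) -> None:
    text = json.dumps(data, indent=1, sort_keys=True)
    if out:
        Path(out).write_text(text)
    else:
        click.echo(text)


@click.group()
@click.option("--log-level", default="warning", show_default=True,
              type=click.Choice(["debug", "info", "warning", "error"]))
def main(log_level: str) -> None:
    """Structural analysis of Markov-blanket linear OU systems."""
    _setup_logging(log_level)


@main.command()
@click.option("--observation", required=True, type=click.Choice(OBSERVATIONS))
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--out", required=True, type=click.Path())
@click.option("--certificate", type=click.Path(), default=None)
def generate(observation: str, seed: int, out: str, certificate: str | None) -> None:
    """Generate a certified counterexample system."""
    cert = generate_counterexample(observation, seed)
    write_system(out, cert.system, include_potential=True)
    if certificate:
        _dump(cert.to_dict(), certificate)
    logger.info("generated %s with seed %d in %d attempts", observation, seed, cert.attempts)


@main.command()
@click.option("--system", "system_path", required=True, type=click.Path(exists=True))
@click.option("--conditions", default="1,2,3", show_default=True)
@click.option("--tol", default=TOL_STRUCTURAL, show_default=True, type=float)
@click.option("--out", type=click.Path(), default=None)
def check(system_path: str, conditions: str, tol: float, out: str | None) -> None:
    """Check blanket conditions on a system file."""
    sysdata = read_system(system_path)
    ids = [int(c) for c in conditions.split(",") if c.strip()]
    report = {str(cid): check_condition(sysdata.system, cid, tol).to_dict() for cid in ids}
    _dump(report, out)


@main.command()
@click.option("--system", "system_path", required=True, type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default=None)
def identities(system_path: str, out: str | None) -> None:
    """Report which flow-rewriting families hold."""
    sysdata = read_system(system_path)
    _dump(identity_residuals(sysdata.system).to_dict(), out)


@main.command()
@click.option("--system", "system_path", required=True, type=click.Path(exists=True))
@click.option("--family", default="diagonal", show_default=True,
              type=click.Choice(MARGINAL_FAMILIES))
@click.option("--probe-c", default=1e6, show_default=True, type=float)
@click.option("--out", type=click.Path(), default=None)
def lemma(system_path: str, family: str, probe_c: float, out: str | None) -> None:
    """Free-energy feasibility analysis (with KL probe when feasible)."""
    sysdata = read_system(system_path)
    feas = lemma_feasibility(sysdata.system, family)
    report = feas.to_dict()
    if feas.status == "ok" and feas.feasible:
        report["probe"] = kl_supremum_probe(sysdata.system, feas, c=probe_c).to_dict()
    _dump(report, out)


@main.command()
@click.option("--system", "system_path", required=True, type=click.Path(exists=True))
@click.option("--order", default=3, show_default=True, type=int)
@click.option("--out", required=True, type=click.Path())
def lift(system_path: str, order: int, out: str) -> None:
    """Lift a system to independent copies and write the lifted system."""
    sysdata = read_system(system_path)
    lifted = lift_generalised(sysdata.system, order)
    write_system(out, lifted.system, include_potential=True)


@main.command()
@click.option("--system", "system_path", required=True, type=click.Path(exists=True))
@click.option("--steps", default=200_000, show_default=True, type=int)
@click.option("--dt", default=0.01, show_default=True, type=float)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--out", type=click.Path(), default=None)
def simulate(system_path: str, steps: int, dt: float, seed: int, out: str | None) -> None:
    """Simulate the SDE and compare empirical with analytic covariance."""
    sysdata = read_system(system_path)
    summary = simulate_em(sysdata.system, n_steps=steps, dt=dt, seed=seed)
    z = validate_empirical(summary, sysdata.system.stationary)
    _dump({
        "n_steps": steps, "dt": dt, "seed": seed, "burn_in": summary.burn_in,
        "min_ess": summary.min_ess,
        "empirical_mean": summary.mean.tolist(),
        "empirical_cov": summary.cov.tolist(),
        "max_abs_z": z.max_abs_z, "passed": z.passed,
    }, out)


@main.command()
@click.option("--system", "system_path", required=True, type=click.Path(exists=True))
@click.option("--tol", default=TOL_STRUCTURAL, show_default=True, type=float)
@click.option("--lift-order", default=None, type=int)
@click.option("--simulate/--no-simulate", "do_sim", default=False, show_default=True)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--out", type=click.Path(), default=None)
def analyze(system_path: str, tol: float, lift_order: int | None, do_sim: bool,
            seed: int, out: str | None) -> None:
    """Run the full structural analysis pipeline."""
    report = run_full_analysis(system_path, tol=tol, lift_order=lift_order,
                               simulate=do_sim, seed=seed)
    _dump(report, out)
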