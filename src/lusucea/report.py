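"""Result writers: delimited tables, human-readable summaries, manifests.

Machine output is full-precision CSV/JSON; rounding happens only in the
human-readable report. Every run writes a manifest recording the command,
a digest of the effective parameter set, the seed and the output paths,
so any artifact can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .engine import CEAResult
from .meta import PooledEffect
from .params import ARMS, ModelParameters, dump_parameters
from .sensitivity import OwsaEntry, PsaSummary, owsa_table

__all__ = [
    "params_digest",
    "write_manifest",
    "cea_result_frame",
    "format_cea_report",
    "write_cea_result",
    "write_owsa",
    "write_psa",
    "format_pooled_effect",
]


def params_digest(params: ModelParameters) -> str:
    """SHA-256 of the canonical serialisation of the effective inputs."""
    return hashlib.sha256(dump_parameters(params).encode()).hexdigest()


def write_manifest(
    out_dir: Path,
    command: str,
    params: ModelParameters,
    seed: int | None,
    outputs: Sequence[str],
    extra: Mapping | None = None,
) -> Path:
    manifest = {
        "command": command,
        "package_version": __version__,
        "params_digest": params_digest(params),
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": list(outputs),
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def cea_result_frame(result: CEAResult) -> pd.DataFrame:
    """Per-arm totals and increments as a tidy table."""
    rows = []
    for arm in ARMS:
        o = result.outcomes[arm]
        rows.append(
            {
                "scenario": result.scenario,
                "strategy": arm,
                "cost_jpy": o.cost,
                "qaly": o.qaly,
                "tree_cost_jpy": o.tree.expected_cost,
                "tree_qaly": o.tree.expected_qaly,
                "tree_survival": o.tree.survival_prob,
                "markov_qaly_per_survivor": o.markov_qaly_per_survivor,
            }
        )
    frame = pd.DataFrame(rows)
    frame["delta_cost_jpy"] = [result.delta_cost, None]
    frame["delta_qaly"] = [result.delta_qaly, None]
    frame["icer_jpy_per_qaly"] = [result.icer, None]
    frame["verdict"] = [result.label, None]
    frame["nmb_jpy"] = [result.nmb_at_threshold, None]
    return frame


def format_cea_report(result: CEAResult) -> str:
    """Aligned human-readable summary of one comparison."""
    lines = [
        f"Scenario {result.scenario}: {result.notes}",
        f"{'strategy':<8}{'cost (JPY)':>16}{'QALYs':>12}",
    ]
    for arm in ARMS:
        o = result.outcomes[arm]
        lines.append(f"{arm:<8}{o.cost:>16,.0f}{o.qaly:>12.4f}")
    lines.append(
        f"increment (LUSU - PT): {result.delta_cost:,.0f} JPY, "
        f"{result.delta_qaly:.4f} QALYs"
    )
    verdict = result.label if result.icer is None else f"ICER {result.icer:,.0f} JPY/QALY"
    lines.append(f"verdict: {verdict}")
    lines.append(
        f"net monetary benefit at {result.threshold:,.0f} JPY/QALY: "
        f"{result.nmb_at_threshold:,.0f} JPY"
    )
    return "\n".join(lines)


def write_cea_result(result: CEAResult, out_dir: Path) -> list[str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"cea_{result.scenario}.csv"
    cea_result_frame(result).to_csv(csv_path, index=False)
    txt_path = out_dir / f"cea_{result.scenario}.txt"
    txt_path.write_text(format_cea_report(result) + "\n")
    return [csv_path.name, txt_path.name]


def write_owsa(entries: Sequence[OwsaEntry], out_dir: Path, top: int | None = None) -> list[str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = owsa_table(entries)
    if top is not None:
        table = table.head(top)
    path = out_dir / "tornado.csv"
    table.to_csv(path, index=False)
    return [path.name]


def write_psa(summary: PsaSummary, out_dir: Path) -> list[str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    draws_path = out_dir / "psa_draws.csv"
    summary.draws.to_csv(draws_path, index=False)
    ceac_path = out_dir / "ceac.csv"
    pd.DataFrame(
        {"threshold_jpy_per_qaly": list(summary.acceptability),
         "p_cost_effective": list(summary.acceptability.values())}
    ).to_csv(ceac_path, index=False)
    summary_path = out_dir / "psa_summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "n_iter": summary.n_iter,
                "seed": summary.seed,
                "p_dominant": summary.p_dominant,
                "acceptability_at_wtp": summary.wtp_acceptability,
            },
            indent=2,
        )
        + "\n"
    )
    return [draws_path.name, ceac_path.name, summary_path.name]


def format_pooled_effect(effect: PooledEffect) -> str:
    return (
        f"pooled OR {effect.or_point:.4f} "
        f"(95% CI {effect.ci_lower:.4f} to {effect.ci_upper:.4f}), "
        f"tau^2 {effect.tau2:.4f}, Q {effect.q:.4f}, k {effect.k_studies}"
    )
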