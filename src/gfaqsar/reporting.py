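"""Model reports: JSON + fixed-width text in the layout of the source tables.

Reports are deterministic — no timestamps or environment details in the
files — so identical inputs and seeds give byte-identical outputs.  The
input file's SHA-256 is echoed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

from .datasets import DescriptorTable
from .regression import FitStats, LinearModel, rank_importance


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def model_report(
    model: LinearModel,
    stats: FitStats,
    table: DescriptorTable,
    *,
    input_checksum: str | None = None,
) -> dict[str, Any]:
    """Assemble the full report of one fitted equation as a plain dict."""
    preds = []
    for rec in table.records:
        pred = model.predict_record(rec)
        row = {"ligand_id": rec.ligand_id, "predicted": round(pred, 3)}
        if rec.pic50_obs is not None:
            row["observed"] = rec.pic50_obs
            row["residual"] = round(rec.pic50_obs - pred, 3)
        preds.append(row)
    return {
        "table": table.name,
        "provenance": model.provenance,
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
        "stats": {
            "n": stats.n,
            "k": stats.k,
            "sse": stats.sse,
            "sst": stats.sst,
            "press": stats.press,
            "r2": stats.r2,
            "r2_adj": stats.r2_adj,
            "q2": stats.q2,
            "f_stat": stats.f_stat,
            "lof": stats.lof,
        },
        "standardized_coefficients": dict(stats.std_coefficients),
        "importance_ranking": rank_importance(stats.std_coefficients)
        if stats.std_coefficients
        else [],
        "predictions": preds,
        "input_sha256": input_checksum,
    }


def render_text(report: dict[str, Any]) -> str:
    """Fixed-width text report mirroring the published statistics line."""
    s = report["stats"]

    def num(v: float | None, nd: int = 3) -> str:
        return "n/a" if v is None else f"{v:.{nd}f}"

    lines = [
        f"Model on table {report['table']!r} ({report['provenance']})",
        "",
        f"N = {s['n']}, LOF = {num(s['lof'])}, R^2 = {num(s['r2'])}, "
        f"R^2_adj = {num(s['r2_adj'])}, R^2_cv = {num(s['q2'])}, F = {num(s['f_stat'], 2)}",
        "",
        f"{'term':<22}{'coefficient':>14}{'standardized':>14}",
        f"{'(intercept)':<22}{report['intercept']:>14.4f}{'':>14}",
    ]
    std = report["standardized_coefficients"]
    for term, coef in report["coefficients"].items():
        lines.append(f"{term:<22}{coef:>14.4f}{std.get(term, float('nan')):>14.4f}")
    if report["importance_ranking"]:
        lines += ["", "importance: " + " > ".join(report["importance_ranking"])]
    lines += ["", f"{'ligand':<8}{'observed':>10}{'predicted':>10}{'residual':>10}"]
    for row in report["predictions"]:
        obs = f"{row['observed']:.3f}" if "observed" in row else ""
        res = f"{row['residual']:.3f}" if "residual" in row else ""
        lines.append(f"{row['ligand_id']:<8}{obs:>10}{row['predicted']:>10.3f}{res:>10}")
    if report.get("input_sha256"):
        lines += ["", f"input sha256: {report['input_sha256']}"]
    return "\n".join(lines) + "\n"


def write_report(report: dict[str, Any], out_dir: str | Path, stem: str = "model") -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / f"{stem}.json"
    text_path = out_dir / f"{stem}.txt"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    text_path.write_text(render_text(report))
    return json_path, text_path


def observed_vs_predicted_plot(report: dict[str, Any], path: str | Path) -> None:
    """Optional scatter of observed vs predicted activities (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = [r["observed"] for r in report["predictions"] if "observed" in r]
    pred = [r["predicted"] for r in report["predictions"] if "observed" in r]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(obs, pred, s=18)
    lo, hi = min(obs + pred), max(obs + pred)
    ax.plot([lo, hi], [lo, hi], lw=1, color="grey")
    ax.set_xlabel("observed pIC50 (mM scale)")
    ax.set_ylabel("predicted pIC50 (mM scale)")
    ax.set_title(f"table {report['table']!r}, R^2 = {report['stats']['r2']:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
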