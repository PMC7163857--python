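"""Report assembly: summary tables, p-value matrices and figures.

The statistical report mirrors the study layout: for every flexion
angle, an all-pairs p-value block over the meniscal states for the in
situ force, and over the three resection states for each alignment
outcome (intact is the zero baseline of the alignment changes and is
not a compared group).  Figures are grouped bar charts of the synthetic
outcomes with significance markers; they are labelled as synthetic
because they visualize simulator output, not measured tissue data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pipeline import RESECTION_STATES, STATES
from .stats import PairwiseTable, RmAnovaResult, rm_anova, tukey_hsd

__all__ = ["OutcomeStats", "outcome_matrix", "run_stats", "write_stats_tables",
           "write_report", "summary_table"]

OUTCOMES = {
    "insitu_force": ("insitu_force", STATES),
    "d_varus": ("d_varus", RESECTION_STATES),
    "d_extrot": ("d_extrot", RESECTION_STATES),
}


@dataclass(frozen=True)
class OutcomeStats:
    """ANOVA + Tukey table for one outcome at one flexion angle."""

    outcome: str
    flexion_angle: float
    states: tuple[str, ...]
    anova: RmAnovaResult
    tukey: PairwiseTable


def outcome_matrix(results: pd.DataFrame, outcome: str, angle: float) -> np.ndarray:
    """Subjects x states matrix for one outcome at one flexion angle."""
    col, states = OUTCOMES[outcome]
    sub = results[results["flexion_angle"] == angle]
    wide = sub.pivot_table(index="specimen", columns="state", values=col,
                           observed=True)
    missing = [s for s in states if s not in wide.columns]
    if missing:
        raise ValueError(f"missing state(s) {missing} for {outcome} at {angle} deg")
    mat = wide[list(states)].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError(f"incomplete cells for {outcome} at {angle} deg")
    return mat


def run_stats(results: pd.DataFrame,
              sphericity_correction: bool = False) -> list[OutcomeStats]:
    """RM-ANOVA + Tukey HSD per outcome per flexion angle."""
    out: list[OutcomeStats] = []
    for angle in sorted(results["flexion_angle"].unique()):
        for outcome, (_, states) in OUTCOMES.items():
            mat = outcome_matrix(results, outcome, angle)
            anova = rm_anova(mat, sphericity_correction=sphericity_correction)
            tukey = tukey_hsd(mat, anova)
            tukey = PairwiseTable(labels=tuple(states), p=tukey.p)
            out.append(OutcomeStats(outcome, float(angle), tuple(states),
                                    anova, tukey))
    return out


def summary_table(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of every outcome per flexion angle x state."""
    return (
        results
        .groupby(["flexion_angle", "state"], observed=True)
        .agg(
            insitu_mean=("insitu_force", "mean"),
            insitu_sd=("insitu_force", "std"),
            d_varus_mean=("d_varus", "mean"),
            d_varus_sd=("d_varus", "std"),
            d_extrot_mean=("d_extrot", "mean"),
            d_extrot_sd=("d_extrot", "std"),
        )
        .reset_index()
    )


def _provenance(seed, config_digest: str | None) -> str:
    return (f"# kneerig {__version__} | seed={seed} | "
            f"config_sha256={config_digest or 'n/a'}")


def config_digest(config_obj) -> str:
    """Stable SHA-256 of a (nested) dataclass configuration."""
    import dataclasses

    def enc(o):
        if dataclasses.is_dataclass(o):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, dict):
            return {k: enc(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o

    blob = json.dumps(enc(config_obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_stats_tables(stats: list[OutcomeStats], path, seed=None,
                       digest: str | None = None, alpha: float = 0.05) -> None:
    """TSV p-value matrices, one block per flexion angle per outcome."""
    lines = [_provenance(seed, digest)]
    for st in stats:
        lines.append(f"## outcome={st.outcome}\tflexion={st.flexion_angle:g} deg\t"
                     f"F={st.anova.F_stat:.4g}\t"
                     f"df=({st.anova.df_treatment},{st.anova.df_error})\t"
                     f"anova_p={st.anova.p_value:.4g}")
        lines.append("\t" + "\t".join(st.states[1:]))
        for i, row_state in enumerate(st.states[:-1]):
            cells = []
            for j in range(1, len(st.states)):
                if j <= i:
                    cells.append("-")
                else:
                    p = st.tukey.p[i, j]
                    mark = "*" if p < alpha else ""
                    cells.append(f"{p:.4g}{mark}")
            lines.append(row_state + "\t" + "\t".join(cells))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_report(results: pd.DataFrame, stats: list[OutcomeStats], out_dir,
                 seed=None, digest: str | None = None, alpha: float = 0.05,
                 make_plots: bool = True) -> dict[str, Path]:
    """Write the summary table, p-value tables and figures; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary = summary_table(results)
    paths["summary"] = out / "summary.tsv"
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed, digest) + "\n")
        summary.to_csv(fh, sep="\t", index=False, float_format="%.4f")

    paths["stats"] = out / "pvalues.tsv"
    write_stats_tables(stats, paths["stats"], seed=seed, digest=digest, alpha=alpha)

    if make_plots:
        paths.update(_plots(results, stats, out, alpha))
    return paths


def _plots(results: pd.DataFrame, stats: list[OutcomeStats], out: Path,
           alpha: float) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    specs = [
        ("insitu_force", "In situ force (N)", "insitu_force.png", STATES),
        ("d_varus", "Varus change vs intact (deg)", "alignment_varus.png",
         RESECTION_STATES),
        ("d_extrot", "External-rotation change vs intact (deg)",
         "alignment_extrot.png", RESECTION_STATES),
    ]
    angles = sorted(results["flexion_angle"].unique())
    for outcome, ylabel, fname, states in specs:
        fig, ax = plt.subplots(figsize=(7, 4))
        width = 0.8 / len(states)
        x = np.arange(len(angles))
        for k, state in enumerate(states):
            sub = results[results["state"] == state]
            means = [sub[sub["flexion_angle"] == a][OUTCOMES[outcome][0]].mean()
                     for a in angles]
            sds = [sub[sub["flexion_angle"] == a][OUTCOMES[outcome][0]].std()
                   for a in angles]
            ax.bar(x + k * width, means, width, yerr=sds, capsize=2, label=state)
        for i, a in enumerate(angles):
            st = next(s for s in stats
                      if s.outcome == outcome and s.flexion_angle == a)
            if st.anova.p_value < alpha:
                ax.annotate("*", (i + 0.4 - width / 2, ax.get_ylim()[1] * 0.95),
                            ha="center", fontsize=14)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels([f"{a:g}°" for a in angles])
        ax.set_xlabel("Knee flexion angle")
        ax.set_ylabel(ylabel)
        ax.set_title(f"{ylabel} — synthetic data")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths[outcome] = path
    return paths
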