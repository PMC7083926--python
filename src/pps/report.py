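"""Rendering of results bundles: text report, Table-2-shaped CSV, violins.

Every number in the report is read from the results bundle; nothing is
recomputed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["render_report", "cells_to_table", "plot_cce_violins"]


def _fmt_bf(d: dict) -> str:
    bound = d.get("bound")
    pre = {"<": "< ", ">": "> "}.get(bound, "")
    return f"BF10 {pre}{d['bf10']:.3g} ({d['band']})"


def _section(lines, title):
    lines.append("")
    lines.append(title)
    lines.append("-" * len(title))


def render_report(bundle: dict) -> str:
    """Human-readable summary of a pipeline results bundle."""
    lines = ["PPS pipeline report", "==================="]
    missing = []

    meta = bundle.get("meta")
    if meta:
        _section(lines, "Run")
        for k in ("seed", "config_hash", "mcmc_profile"):
            if k in meta:
                lines.append(f"  {k}: {meta[k]}")

    casc = bundle.get("cascade")
    if casc:
        _section(lines, "Exclusion cascade")
        lines.append(f"  input trials: {casc['n_input_trials']}")
        lines.append(f"  accuracy-gate failures: "
                     f"{casc['gate_failures'] or 'none'}")
        lines.append(f"  RTs < 100 ms removed: {casc['n_rt_removed']}")
        lines.append(f"  outliers removed: "
                     f"{100 * casc['outlier_fraction']:.2f}% of IE entries")
        lines.append(f"  IE entries retained: {casc['n_ie_entries']}")
    else:
        missing.append("cascade")

    base = bundle.get("baseline")
    if base:
        _section(lines, "Baseline vs follow-up")
        lines.append(f"  Laterality x Condition interaction: "
                     f"{_fmt_bf(base['interaction_bf'])}")
        lines.append(f"  merge into 'NoStimulation': "
                     f"{'yes' if base['merge_recommended'] else 'no'}")
    else:
        missing.append("baseline")

    cce = bundle.get("cce")
    if cce:
        _section(lines, "CCE model (omnibus)")
        for term, d in cce["omnibus"].items():
            lines.append(f"  {term}: {_fmt_bf(d)}")
        cells = pd.DataFrame(cce["cells"])
        if len(cells):
            lines.append("")
            lines.append("  CCE estimates, ms "
                         "(mode [99% HPDI]), Condition x Laterality x Group:")
            lines.append("  " + cells_to_table(cells).to_string())
        contrasts = pd.DataFrame(cce["contrasts"])
        if len(contrasts):
            lines.append("")
            lines.append("  Unilateral - Bilateral contrasts (post hoc):")
            for _, r in contrasts.iterrows():
                lines.append(
                    f"    {r['group']:>3} {r['condition']:<14} "
                    f"BF10 {r['bf10']:.3g} ({r['band']}); "
                    f"{r['mode']:.1f} ms [{r['hpdi_lo']:.1f}, "
                    f"{r['hpdi_hi']:.1f}]")
        elif not cce.get("posthoc_gated", True):
            lines.append("  post-hoc contrasts not run: no "
                         "laterality-involving term reached BF10 >= 3")
    else:
        missing.append("cce")

    fb = bundle.get("feedback")
    if fb:
        _section(lines, "Movement verbal feedback")
        for term, d in fb["model_bfs"].items():
            lines.append(f"  {term}: {_fmt_bf(d)}")
        lines.append("  accuracy vs 85%-correct point hypothesis "
                     "(closed-form BF against guessing):")
        for r in fb["point_bfs"]:
            lines.append(f"    {r['group']:>3} {r['condition']:<6} "
                         f"{r['k']}/{r['n']}  BF10 {r['bf10']:.3g} "
                         f"({r['band']})")
        if fb.get("pairwise"):
            lines.append("  pairwise condition refits (no multiplicity "
                         "adjustment; BFs compare models directly):")
            for r in fb["pairwise"]:
                lines.append(f"    {r['group']:>3} {r['a']} vs {r['b']}: "
                             f"BF10 {r['bf10']:.3g} ({r['band']})")
    else:
        missing.append("feedback")

    for key, label in (("covary_physio", "Covariation: SCL / RSA"),
                       ("covary_bpq", "Covariation: BPQ body awareness"),
                       ("covary_clinical", "Covariation: AIS / NLI")):
        cov = bundle.get(key)
        if not cov:
            continue
        _section(lines, label)
        for term, d in cov["bfs"].items():
            lines.append(f"  {term}: {_fmt_bf(d)}")
        for r in cov["slopes"]:
            lines.append(
                f"  slope {r['covariate']} | {r['condition']}: "
                f"Mo = {r['mode']:.2f} [{r['hpdi_lo']:.2f}, "
                f"{r['hpdi_hi']:.2f}] (standardized)")

    # convergence across all sections
    warn = []
    for key in ("baseline", "cce", "feedback", "covary_physio",
                "covary_bpq", "covary_clinical"):
        sec = bundle.get(key)
        if not sec:
            continue
        for name, v in (sec.get("rhat") or {}).items():
            if not v < 1.1:
                warn.append(f"{key}: {name} (R-hat = {v:.3f})")
    _section(lines, "Convergence")
    if warn:
        lines.append("  WARNING - parameters with R-hat >= 1.1:")
        lines.extend(f"    {w}" for w in warn)
    else:
        lines.append("  all monitored R-hat < 1.1")

    if missing:
        _section(lines, "Missing sections")
        lines.extend(f"  {m}" for m in missing)
    return "\n".join(lines) + "\n"


def cells_to_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Reshape cell estimates to Condition x Laterality rows and Group
    columns, each cell "mode [lo-hi]"."""
    c = cells.copy()
    c["text"] = [f"{m:.1f} [{lo:.1f}, {hi:.1f}]" for m, lo, hi in
                 zip(c["mode"], c["hpdi_lo"], c["hpdi_hi"])]
    return c.pivot_table(index=["condition", "laterality"],
                         columns="group", values="text", aggfunc="first")


def plot_cce_violins(fit, path, groups=None, conds=None):
    """Violin plot of posterior CCE distributions per condition x group,
    split by laterality (PNG/SVG by file extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .analyses import _cell_grid

    if groups is None:
        groups = sorted(fit.levels.get("group", [])) or ["all"]
    if conds is None:
        conds = sorted(fit.levels.get("condition", [])) or ["all"]
    grid = _cell_grid(groups, conds)
    draws = fit.predict_fixed(grid)
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 4),
                             sharey=True, squeeze=False)
    for gi, g in enumerate(groups):
        ax = axes[0][gi]
        data, pos, colors = [], [], []
        for ci, c in enumerate(conds):
            for li, lat in enumerate(("Unilateral", "Bilateral")):
                sel = grid[(grid["group"] == g) & (grid["condition"] == c)
                           & (grid["laterality"] == lat)].index[0]
                data.append(draws[:, sel])
                pos.append(ci + (li - 0.5) * 0.35)
                colors.append("C0" if lat == "Unilateral" else "C1")
        parts = ax.violinplot(data, positions=pos, widths=0.3,
                              showmedians=True)
        for body, col in zip(parts["bodies"], colors):
            body.set_facecolor(col)
        ax.set_title(g)
        ax.set_xticks(range(len(conds)))
        ax.set_xticklabels(conds, rotation=45, ha="right")
        if gi == 0:
            ax.set_ylabel("CCE (ms)")
        ax.axhline(0.0, color="grey", lw=0.5)
    fig.suptitle("Posterior CCE (blue: unilateral, orange: bilateral)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
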