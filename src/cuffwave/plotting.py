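"""Plot helpers for sweep summaries and sensitivity results.

These render the CSV tables produced by the CLI into simple matplotlib
panels (waveforms per cuff pressure, relative-change curves vs Pcuff,
Sobol' index bars).  Import is deferred to keep headless pipelines light.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_sweep_summary(summary_csv: str | Path, out_png: str | Path) -> None:
    """Relative central changes vs cuff pressure (one panel per metric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(summary_csv)
    metrics = [c for c in ("dMAP_pct", "dSP_pct", "dDP_pct", "dQbar_pct")
               if c in df.columns]
    probes = sorted(df["probe"].unique())
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2),
                             sharex=True)
    for ax, metric in zip(axes if len(metrics) > 1 else [axes], metrics):
        for probe in probes:
            d = df[df["probe"] == probe].sort_values("Pcuff_mmHg")
            ax.plot(d["Pcuff_mmHg"], d[metric], marker="o", ms=3, label=probe)
        ax.set_xlabel("cuff pressure (mmHg)")
        ax.set_ylabel(metric.replace("_pct", " (%)"))
        ax.axhline(0.0, color="0.7", lw=0.8)
    (axes[0] if len(metrics) > 1 else axes).legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)


def plot_sobol_indices(sobol_csv: str | Path, out_png: str | Path) -> None:
    """First-order indices with 95% CIs, one panel per output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(sobol_csv)
    outputs = sorted(df["output"].unique())
    fig, axes = plt.subplots(len(outputs), 1, figsize=(7, 3 * len(outputs)))
    axes = axes if len(outputs) > 1 else [axes]
    for ax, output in zip(axes, outputs):
        d = df[df["output"] == output]
        x = range(len(d))
        ax.bar(x, d["S1"], color="0.4")
        ax.errorbar(x, d["S1"],
                    yerr=[d["S1"] - d["ci_low"], d["ci_high"] - d["S1"]],
                    fmt="none", ecolor="red", capsize=2)
        ax.set_xticks(list(x), d["parameter"], rotation=45, fontsize=7)
        ax.set_ylabel(f"S1 ({output})")
        ax.axhline(0.0, color="0.7", lw=0.8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
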