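"""Figure exports: per-model CV boxplots and confidence-tier histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_cv_boxplots(evaluations: dict, metric: str = "balanced_accuracy",
                     out_path=None):
    """Boxplots of per-(fold, repeat) macro metric values, one per model.

    ``evaluations`` maps model name -> EvaluationResult.
    """
    names, series = [], []
    for name, ev in evaluations.items():
        vals = [fr.report.macro[metric] for fr in ev.fold_reports
                if fr.report is not None]
        names.append(name)
        series.append(vals)
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    ax.boxplot(series, tick_labels=names)
    ax.set_ylabel(f"macro {metric.replace('_', ' ')}")
    ax.set_ylim(0, 1.05)
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_confidence_histogram(bins: pd.DataFrame, out_path=None):
    """Stacked correct/incorrect counts per confidence tier.

    ``bins`` is the output of ``confidence.bin_error_rates``.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(bins))
    correct = bins["n"] - bins["n_incorrect"]
    ax.bar(x, correct, label="correct", color="#4c9f70")
    ax.bar(x, bins["n_incorrect"], bottom=correct, label="incorrect",
           color="#c0504d")
    ax.set_xticks(x, bins["tier"])
    ax.set_xlabel("confidence tier (max class probability)")
    ax.set_ylabel("predictions")
    ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
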