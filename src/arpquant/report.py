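"""Cross-strain aggregation, group statistics, and report emission.

Group comparisons follow the standard scheme for these assays: an ordinary
one-way ANOVA across strains with Dunnett's many-to-one test for each
strain against the designated control.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "anova_dunnett",
    "percent_decrease",
    "build_report",
]


@dataclass
class GroupComparison:
    """One-way ANOVA plus Dunnett many-to-one comparisons against a control."""

    control: str
    labels: list[str]  # non-control groups, comparison order
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    f_statistic: float
    p_omnibus: float
    p_adjusted: dict[str, float]  # per non-control group, vs control

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.p_adjusted.values()):
            raise ValueError("adjusted p values must lie in [0, 1]")


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    seed: int | None = 0,
) -> GroupComparison:
    """Ordinary one-way ANOVA with Dunnett's test against ``control``.

    Every group needs n >= 2 and the pooled within-group variance must be
    positive. Dunnett adjusted p values come from the multivariate-t
    distribution (fixed seed for its numerical integration, so results are
    reproducible).
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    if all(np.allclose(a, a[0]) for a in arrays.values()):
        raise ValueError("degenerate within-group variance")
    labels = [k for k in arrays if k != control]
    f_stat, p_omnibus = stats.f_oneway(*arrays.values())
    res = stats.dunnett(
        *[arrays[k] for k in labels],
        control=arrays[control],
        rng=np.random.default_rng(seed),
    )
    return GroupComparison(
        control=control,
        labels=labels,
        n={k: int(a.size) for k, a in arrays.items()},
        mean={k: float(a.mean()) for k, a in arrays.items()},
        sd={k: float(a.std(ddof=1)) for k, a in arrays.items()},
        f_statistic=float(f_stat),
        p_omnibus=float(p_omnibus),
        p_adjusted={k: float(p) for k, p in zip(labels, res.pvalue)},
    )


def percent_decrease(value: float, reference: float) -> float:
    """Decrease of ``value`` relative to ``reference``, in percent."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return (reference - value) / reference * 100.0


def _config_hash(config_json: str) -> str:
    return hashlib.sha256(config_json.encode()).hexdigest()[:16]


def build_report(
    outputs: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config_json: str = "{}",
    seed: int | None = None,
    make_plots: bool = False,
) -> dict:
    """Write stage outputs as CSVs plus a JSON manifest (and optional plots).

    ``outputs`` maps table names (e.g. ``strain_summary``, ``velocity``,
    ``binding_fits``) to DataFrames. Missing stages are simply noted in the
    manifest; empty mappings are an error. Generation is deterministic for
    fixed inputs: CSVs are byte-identical across re-runs.
    """
    if not outputs:
        raise ValueError("no stage outputs to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in sorted(outputs.items()):
        if not isinstance(df, pd.DataFrame):
            raise TypeError(f"stage output {name!r} is not a DataFrame")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.9g")
        written[name] = path.name
    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for name, df in sorted(outputs.items()):
            numeric = df.select_dtypes("number")
            if numeric.empty:
                continue
            fig, ax = plt.subplots(figsize=(5, 3.5))
            numeric.plot(ax=ax)
            ax.set_title(name)
            fig.tight_layout()
            fig.savefig(out_dir / f"{name}.svg")
            plt.close(fig)
    manifest = {
        "tables": written,
        "absent_stages": sorted(
            set(["strain_summary", "velocity", "angular", "bundles",
                 "binding_fits", "titration_fits"]) - set(written)),
        "config_hash": _config_hash(config_json),
        "seed": seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest
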