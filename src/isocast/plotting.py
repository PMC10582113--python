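"""Minimal biplot figure: δ¹³C (x) vs δ¹⁵N (y), one marker per group,
optional standard-ellipse outlines."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .datatypes import CommunityDataset
from .ellipse import EllipseNiche, ellipse_boundary


def make_biplot(
    community: CommunityDataset,
    ellipses: Mapping[str, EllipseNiche] | None = None,
    output: str | Path | Sequence[str | Path] = "biplot.png",
    coverage: float | None = None,
) -> list[Path]:
    """Scatter the community's group means with optional niche ellipses.

    ``output`` may be one path or several (e.g. PNG and SVG); every file
    is written.  Returns the written paths.
    """
    if not community.summaries:
        raise ValueError("community has no groups to plot")
    fig, ax = plt.subplots(figsize=(7, 5))
    for s in community.summaries:
        ax.errorbar(
            s.mean13C,
            s.mean15N,
            xerr=s.sd13C or 0.0,
            yerr=s.sd15N or 0.0,
            fmt="o",
            capsize=2,
            label=s.taxon,
        )
    if ellipses:
        kwargs = {} if coverage is None else {"coverage": coverage}
        for label, niche in ellipses.items():
            ring = ellipse_boundary(niche, **kwargs)
            ax.plot(ring[:, 0], ring[:, 1], lw=1, label=f"{label} ellipse")
    ax.set_xlabel("δ¹³C (‰)")
    ax.set_ylabel("δ¹⁵N (‰)")
    ax.legend(fontsize=6, ncol=2, loc="best")
    fig.tight_layout()
    paths = [output] if isinstance(output, (str, Path)) else list(output)
    written = []
    for p in paths:
        p = Path(p)
        fig.savefig(p, dpi=150)
        written.append(p)
    plt.close(fig)
    return written
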