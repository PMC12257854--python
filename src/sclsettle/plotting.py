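"""Figure helpers: settling curves, polar thickness heat maps, scheme schematic."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .regions import DEFAULT_SCHEME, SECTORS


def plot_settling_curves(summary, path=None, value="mean", err="sem"):
    """Group-mean thickness vs time, one line per group (zonal summary in)."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for (group, region), d in summary.groupby(["group", "region"]):
        d = d.sort_values("time_min")
        ax.errorbar(d["time_min"], d[value], yerr=d[err],
                    marker="o", capsize=3, label=f"{group} {region}")
    ax.set_xlabel("time after lens application (min)")
    ax.set_ylabel("fluid reservoir thickness (um)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_thickness_map(pmap, path=None, title=None):
    """Polar heat map of a reconstructed thickness map."""
    fig, ax = plt.subplots(subplot_kw=dict(projection="polar"), figsize=(5, 4.5))
    g = pmap.grid
    theta_edges = np.deg2rad(np.arange(g.n_theta + 1) * g.dtheta - g.dtheta / 2)
    r_edges = np.arange(g.n_r + 1) * g.dr
    pc = ax.pcolormesh(theta_edges, r_edges, pmap.thickness_um, shading="flat")
    fig.colorbar(pc, ax=ax, label="thickness (um)")
    ax.set_theta_zero_location("E")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_region_schematic(path=None, scheme=DEFAULT_SCHEME):
    """Schematic of the 17-region scheme (annuli + sector labels)."""
    fig, ax = plt.subplots(subplot_kw=dict(projection="polar"), figsize=(4.5, 4.5))
    for radius in (scheme.central_radius, scheme.mid_radius, scheme.outer_radius):
        ax.plot(np.linspace(0, 2 * np.pi, 181), np.full(181, radius), "k-", lw=0.8)
    for k in range(8):
        ang = np.deg2rad(k * 45 + 22.5)
        ax.plot([ang, ang], [scheme.central_radius, scheme.outer_radius], "k-", lw=0.6)
    ax.text(0, 0, "C", ha="center", va="center")
    for k, s in enumerate(SECTORS):
        ang = np.deg2rad(k * 45)
        ax.text(ang, 3.5, f"M-{s}", ha="center", va="center", fontsize=7)
        ax.text(ang, 5.5, f"P-{s}", ha="center", va="center", fontsize=6)
    ax.set_theta_zero_location("E")
    ax.set_rticks([])
    ax.set_xticks([])
    ax.set_rmax(scheme.outer_radius)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
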