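"""Figure rendering for trajectories and degree-change diagnostics.

Matplotlib is imported lazily so that headless analysis runs never touch a
plotting backend. All functions write files and return the output paths.
"""

from __future__ import annotations

from pathlib import Path


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_trajectory(table, outdir, fmt: str = "png") -> list:
    """Entropy/temperature/energy time series plus the entropy-energy trace."""
    plt = _plt()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = []

    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
    x = range(len(table.states))
    axes[0].plot(x, table.states["H"], lw=0.8)
    axes[0].set_ylabel("entropy H")
    xt = range(1, len(table.states))
    axes[1].plot(xt, table.transitions["T"], lw=0.8, color="tab:red")
    axes[1].set_ylabel("temperature T")
    axes[2].plot(x, table.states["U"], lw=0.8, color="tab:green")
    axes[2].set_ylabel("internal energy U")
    axes[2].set_xlabel("snapshot index")
    path = outdir / f"trajectory_timeseries.{fmt}"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    out.append(path)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot(table.states["H"], table.states["U"], "-o", ms=3, lw=0.6)
    ax.set_xlabel("entropy H")
    ax.set_ylabel("internal energy U")
    path = outdir / f"entropy_energy_trace.{fmt}"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    out.append(path)
    return out


def plot_degree_change(table, outdir, fmt: str = "png") -> list:
    """Scatter of delta_v versus d_u for edge-connected node pairs."""
    plt = _plt()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(table["d_u"], table["delta_v"], s=8, alpha=0.5)
    ax.set_xlabel("degree d_u")
    ax.set_ylabel("degree change delta_v")
    path = outdir / f"degree_change_scatter.{fmt}"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return [path]


def plot_variance_profile(profile: dict, outdir, fmt: str = "png") -> list:
    """Variance of the degree change as a function of degree."""
    plt = _plt()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 5))
    degrees = sorted(profile)
    ax.plot(degrees, [profile[d] for d in degrees], "o-", ms=4)
    ax.set_xlabel("degree d_u")
    ax.set_ylabel("var(delta_v)")
    path = outdir / f"degree_change_variance.{fmt}"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return [path]
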