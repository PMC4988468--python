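"""Circular statistics for nucleus-Golgi polarity angles.

The nucleus→Golgi axis proxies the polarity/migration direction of a
mesenchymal cell: line segments from nucleus centre to Golgi centre are
projected onto the frontal (section) plane and the projected direction
recorded as an angle.  Angles use the anatomical convention 0° = dorsal,
90° = lateral, 180° = ventral in image coordinates (y down), i.e.
``angle = atan2(dx, -dy)``; the convention is configurable per sample.

Uniformity is tested with Watson's one-sample U² and homogeneity of two
samples with Watson's rank-based two-sample U².  Both statistics are
rotation invariant, which is the property that makes them appropriate
for circular data.  P-values come from the shared asymptotic series

    p = 2 * sum_{m>=1} (-1)^(m-1) * exp(-2 m^2 pi^2 U^2)

or from Monte-Carlo / permutation resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "OrientationSample",
    "RosetteHistogram",
    "CircularTestResult",
    "nucleus_golgi_angle",
    "angles_from_pairs",
    "remap_to_distal_edge",
    "rosette",
    "circular_mean",
    "watson_u2_uniform",
    "watson_two_sample",
    "annotate_significance",
]

MIN_PROJECTION_UM = 0.5


@dataclass
class OrientationSample:
    """Frontal-plane angles in degrees [0, 360) plus the axis convention used."""

    angles: np.ndarray
    convention: str = "0=dorsal,90=lateral,180=ventral"
    excluded_count: int = 0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float) % 360.0

    def __len__(self) -> int:
        return len(self.angles)


@dataclass
class RosetteHistogram:
    """30° rose-diagram bins with area-true (square-root) radii.

    Radii are sqrt(counts) so that plotted sector *area* is proportional
    to frequency; plotting raw counts as radius would exaggerate small
    differences quadratically.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    radii: np.ndarray


@dataclass
class CircularTestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    m: int | None = None


def nucleus_golgi_angle(
    nucleus_xyz, golgi_xyz, convention: str = "0=dorsal,90=lateral,180=ventral",
    min_projection_um: float = MIN_PROJECTION_UM,
) -> float | None:
    """Frontal-plane angle of the nucleus→Golgi vector, or None if excluded.

    The frontal plane is the section (x-y) plane; the through-plane (z,
    antero-posterior) component is discarded.  Projections shorter than
    ``min_projection_um`` carry no reliable direction and are excluded.
    """
    nucleus = np.asarray(nucleus_xyz, dtype=float)
    golgi = np.asarray(golgi_xyz, dtype=float)
    dx, dy = golgi[0] - nucleus[0], golgi[1] - nucleus[1]
    if np.hypot(dx, dy) < min_projection_um:
        return None
    return float(np.degrees(np.arctan2(dx, -dy)) % 360.0)


def angles_from_pairs(nuclei_xyz: np.ndarray, golgi_xyz: np.ndarray, **kwargs) -> OrientationSample:
    """Vector form of :func:`nucleus_golgi_angle`; excluded pairs are counted."""
    angles = []
    excluded = 0
    for nu, go in zip(np.atleast_2d(nuclei_xyz), np.atleast_2d(golgi_xyz)):
        a = nucleus_golgi_angle(nu, go, **kwargs)
        if a is None:
            excluded += 1
        else:
            angles.append(a)
    return OrientationSample(np.array(angles), excluded_count=excluded)


def remap_to_distal_edge(sample: OrientationSample, distal_edge_angle: float) -> OrientationSample:
    """Rotate angles so the distal-edge direction maps to 180°.

    In elevated shelves the distal edge points medially rather than
    ventrally; re-referencing makes rosettes comparable across stages.
    Circular test statistics are invariant under this rotation.
    """
    return OrientationSample(
        (sample.angles - distal_edge_angle + 180.0) % 360.0,
        convention=f"{sample.convention}; remapped so distal edge = 180°",
        excluded_count=sample.excluded_count,
    )


def rosette(sample: OrientationSample, bin_width_deg: float = 30.0) -> RosetteHistogram:
    """Bin angles into half-open 30° sectors with radii = sqrt(counts)."""
    if len(sample) == 0:
        raise ValueError("cannot build a rosette from an empty sample")
    edges = np.arange(0.0, 360.0 + bin_width_deg / 2, bin_width_deg)
    counts, _ = np.histogram(sample.angles, bins=edges)
    return RosetteHistogram(bin_edges=edges, counts=counts, radii=np.sqrt(counts.astype(float)))


def plot_rosette(hist: RosetteHistogram, ax=None, p_value: float | None = None, title: str = ""):
    """Polar rose diagram; sector area proportional to count.  Returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.deg2rad((hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2)
    width = np.deg2rad(np.diff(hist.bin_edges))
    sig = annotate_significance([p_value])[0] if p_value is not None else ""
    colour = {"<0.001": "#b2182b", "<0.01": "#ef8a62", "<0.05": "#fddbc7"}.get(sig, "#9ecae1")
    ax.bar(centers, hist.radii, width=width, bottom=0.0, color=colour, edgecolor="k", linewidth=0.5)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_yticklabels([])
    if title or sig:
        ax.set_title(f"{title} {sig}".strip())
    return ax


def circular_mean(sample: OrientationSample | np.ndarray) -> tuple[float, float]:
    """Mean direction (degrees) and resultant length R̄ in [0, 1].

    When R̄ < 1e-12 the mean direction is undefined and NaN is returned.
    """
    ang = sample.angles if isinstance(sample, OrientationSample) else np.asarray(sample, dtype=float)
    if len(ang) == 0:
        raise ValueError("empty sample")
    rad = np.deg2rad(ang)
    c, s = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    rbar = float(np.hypot(c, s))
    if rbar < 1e-12:
        return float("nan"), rbar
    return float(np.degrees(np.arctan2(s, c)) % 360.0), rbar


def _watson_series_pvalue(u2: float, tol: float = 1e-10) -> float:
    """Asymptotic tail probability 2*sum((-1)^(m-1) exp(-2 m^2 pi^2 U^2))."""
    if u2 <= 0:
        return 1.0
    total = 0.0
    for m in range(1, 1000):
        term = np.exp(-2.0 * m**2 * np.pi**2 * u2)
        if term < tol:
            break
        total += (-1) ** (m - 1) * term
    # the truncated series cannot resolve tail masses below its term tolerance
    return float(min(max(2.0 * total, tol), 1.0))


def watson_u2_statistic(angles_deg: np.ndarray) -> float:
    """One-sample Watson U² against the circular uniform distribution."""
    u = np.sort(np.asarray(angles_deg, dtype=float) % 360.0) / 360.0
    n = len(u)
    i = np.arange(1, n + 1)
    dev = u - u.mean() - (2 * i - 1) / (2 * n) + 0.5
    return float(np.sum(dev**2) + 1.0 / (12 * n))


def watson_u2_uniform(
    sample: OrientationSample | np.ndarray,
    method: str = "asymptotic",
    n_sim: int = 9999,
    seed: int | None = None,
) -> CircularTestResult:
    """Watson's U² test of circular uniformity.

    ``method='asymptotic'`` uses the exponential series (good for n >= 8);
    ``method='monte_carlo'`` resamples uniform angles of the same size.
    """
    ang = sample.angles if isinstance(sample, OrientationSample) else np.asarray(sample, dtype=float)
    n = len(ang)
    if n < 2:
        raise ValueError("need at least 2 angles")
    u2 = watson_u2_statistic(ang)
    if method == "asymptotic":
        p = _watson_series_pvalue(u2)
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        null = np.array([watson_u2_statistic(rng.uniform(0, 360, n)) for _ in range(n_sim)])
        p = (1.0 + np.sum(null >= u2)) / (n_sim + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CircularTestResult(statistic=u2, p_value=float(p), method=method, n=n)


def _two_sample_u2(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-based two-sample Watson U² = nm/N² * sum_k (d_k - d̄)².

    d_k is the difference between the two empirical CDFs at the k-th
    pooled ordered observation; tied pooled values are handled by
    assigning every member of a tie group the CDF difference at the end
    of the group (the midrank convention for step functions).
    """
    a = np.sort(np.asarray(a, dtype=float) % 360.0)
    b = np.sort(np.asarray(b, dtype=float) % 360.0)
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    source = np.concatenate([np.zeros(n, dtype=int), np.ones(m, dtype=int)])
    order = np.argsort(pooled, kind="mergesort")
    pooled, source = pooled[order], source[order]
    N = n + m
    steps_a = np.cumsum(source == 0) / n
    steps_b = np.cumsum(source == 1) / m
    d = steps_a - steps_b
    # ties across samples: every member of a tie group takes the group-final d
    for start in range(N - 1, 0, -1):
        if pooled[start] == pooled[start - 1]:
            d[start - 1] = d[start]
    dbar = d.mean()
    return float(n * m / N**2 * np.sum((d - dbar) ** 2))


def watson_two_sample(
    sample_a: OrientationSample | np.ndarray,
    sample_b: OrientationSample | np.ndarray,
    method: str = "asymptotic",
    n_perm: int = 9999,
    seed: int | None = None,
) -> CircularTestResult:
    """Watson's two-sample U² test of homogeneity of two angle samples.

    The asymptotic p-value reuses the one-sample exponential series;
    ``method='permutation'`` permutes the pooled sample labels (seeded).
    """
    a = sample_a.angles if isinstance(sample_a, OrientationSample) else np.asarray(sample_a, dtype=float)
    b = sample_b.angles if isinstance(sample_b, OrientationSample) else np.asarray(sample_b, dtype=float)
    n, m = len(a), len(b)
    if n < 2 or m < 2:
        raise ValueError("need at least 2 angles per sample")
    u2 = _two_sample_u2(a, b)
    if method == "asymptotic":
        p = _watson_series_pvalue(u2)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            p = 1.0
        else:
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                if _two_sample_u2(perm[:n], perm[n:]) >= u2 - 1e-15:
                    count += 1
            p = (count + 1.0) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CircularTestResult(statistic=u2, p_value=float(p), method=method, n=n, m=m)


def annotate_significance(p_values) -> list[str]:
    """Map p-values to the rosette display classes '<0.001', '<0.01', '<0.05' or ''."""
    out = []
    for p in p_values:
        p = p.p_value if isinstance(p, CircularTestResult) else p
        if p is None or not np.isfinite(p):
            out.append("")
        elif p < 0.001:
            out.append("<0.001")
        elif p < 0.01:
            out.append("<0.01")
        elif p < 0.05:
            out.append("<0.05")
        else:
            out.append("")
    return out
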