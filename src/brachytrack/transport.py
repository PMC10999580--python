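"""Simplified photon transport through the diverging collimator.

Produces per-panel 38x38 count images from a :class:`~brachytrack.geometry.SourceState`
by pure geometric collimation: photons are emitted isotropically from the
Ir-192 capsule, and a photon is detected by pixel ``(i, j)`` iff its straight
path threads the matching collimator hole (enters through the hole's
patient-side aperture and leaves through its detector-side aperture).  The
energy window and scintillator stopping power are collapsed into a single
``detection_efficiency`` factor; phantom scatter and the Ir-192 decay
spectrum are not modeled.

Two routes are provided:

* :func:`expected_image` - deterministic expected counts, computed by exact
  solid-angle integration of each hole's acceptance over a sub-sampled
  source volume;
* :func:`simulate_image` - Monte Carlo sampling with Poisson counting
  statistics whose mean converges to :func:`expected_image`.

Optionally, septal penetration adds an attenuated (``exp(-mu * l)``)
contribution for photons whose path crosses tungsten.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .geometry import Panel, SourceState, SystemLayout

__all__ = [
    "TransportConfig",
    "CountImage",
    "expected_image",
    "simulate_image",
    "septal_transmission",
    "acquire_all",
    "source_sample_points",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class TransportConfig:
    """Knobs of the transport model.

    ``emitted_photons`` fixes the total number of emissions; when ``None`` it
    is taken as ``activity_bq * exposure_time`` of the source.  ``n_photons``
    is the Monte Carlo sample budget (importance-sampled toward the panel),
    independent of the physical emission count.  ``ambient_background`` is a
    flat expected count per pixel emulating the room/scatter pedestal that
    the geometric model otherwise lacks.
    """

    n_photons: int = 1_000_000
    detection_efficiency: float = 1.0
    septal_penetration: bool = False
    attenuation_coeff: float | None = None
    rng_seed: int = 0
    emitted_photons: float | None = None
    source_subsamples: int = 96
    ambient_background: float = 0.0
    septal_samples: int = 16

    def __post_init__(self) -> None:
        if self.n_photons < 0:
            raise ConfigurationError("n_photons must be >= 0")
        if not 0.0 < self.detection_efficiency <= 1.0:
            raise ConfigurationError("detection_efficiency must lie in (0, 1]")
        if self.ambient_background < 0:
            raise ConfigurationError("ambient_background must be >= 0")

    def emitted(self, source: SourceState) -> float:
        if self.emitted_photons is not None:
            return float(self.emitted_photons)
        return float(source.activity_bq * source.exposure_time)


@dataclass
class CountImage:
    """A 2D photon-count image from one panel.

    ``counts[i, j]``: ``i`` runs along the panel-local v direction (world z
    for ring panels), ``j`` along the local u direction.
    """

    counts: np.ndarray
    panel_id: int = 0
    exposure_time: float = 1.0
    rng_seed: int | None = None
    model_tag: str = "monte-carlo"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ConfigurationError("counts must be a 2D array")
        if np.any(c < 0):
            raise ConfigurationError("counts must be nonnegative")
        self.counts = c


def septal_transmission(path_length: float | np.ndarray, attenuation_coeff: float) -> float | np.ndarray:
    """Probability that a photon survives ``path_length`` mm of tungsten."""
    ell = np.asarray(path_length, dtype=float)
    if np.any(ell < 0):
        raise ValueError("path length must be >= 0")
    out = np.exp(-attenuation_coeff * ell)
    return float(out) if np.isscalar(path_length) else out


def source_sample_points(source: SourceState, n: int) -> np.ndarray:
    """Deterministic uniform sub-sampling of the source cylinder (world frame).

    Points are laid out on axial layers with a sunflower (golden-angle)
    pattern in each disc, which fills the cylinder evenly for any budget.
    """
    if n <= 1:
        return source.center[None, :]
    nz = max(1, int(round(n ** (1.0 / 3.0))))
    m = max(1, n // nz)
    k = np.arange(m)
    r = (source.diameter / 2.0) * np.sqrt((k + 0.5) / m)
    phi = k * _GOLDEN_ANGLE
    x, y = r * np.cos(phi), r * np.sin(phi)
    zs = ((np.arange(nz) + 0.5) / nz - 0.5) * source.length
    # orthonormal frame around the capsule axis
    a = source.axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    pts = []
    for z in zs:
        pts.append(source.center + np.outer(x, e1) + np.outer(y, e2) + z * a)
    return np.vstack(pts)


def _rect_solid_angle(x1, x2, y1, y2, dz):
    """Solid angle of the axis-aligned rectangle [x1,x2]x[y1,y2] on a plane at
    perpendicular distance ``dz``, seen from the origin (coordinates relative
    to the viewpoint's foot on the plane)."""

    def corner(x, y):
        return np.arctan2(x * y, dz * np.sqrt(x * x + y * y + dz * dz))

    return corner(x2, y2) - corner(x1, y2) - corner(x2, y1) + corner(x1, y1)


def _tungsten_path(panel: Panel, start: np.ndarray, end: np.ndarray, k: int) -> np.ndarray:
    """Tungsten path length (mm) along chords through the collimator.

    ``start``/``end`` are (n, 3) panel-local points on the entrance and
    detector-side faces.  The diverging hole lattice at local height ``z``
    is the detector-face lattice scaled by ``z / F``, so a point is inside an
    open hole iff its focal-scaled coordinates fall within a hole opening.
    Chords are sampled at ``k`` interior points; anything outside the hole
    array's footprint counts as tungsten.
    """
    col = panel.collimator
    F = panel.focal_len
    n_holes = col.holes_per_side
    off0 = -(n_holes - 1) / 2.0 * col.pitch
    taus = (np.arange(k) + 0.5) / k
    frac_open = np.zeros(start.shape[0])
    for t in taus:
        p = start + t * (end - start)
        q = p[:, :2] * (F / p[:, 2:3])
        idx = np.rint((q - off0) / col.pitch)
        inside_grid = np.all((idx >= 0) & (idx < n_holes), axis=1)
        centers = off0 + idx * col.pitch
        in_hole = np.all(np.abs(q - centers) <= col.hole_size_d / 2.0, axis=1)
        frac_open += (inside_grid & in_hole) / k
    chord = np.linalg.norm(end - start, axis=1)
    return chord * (1.0 - frac_open)


def expected_image(panel: Panel, source: SourceState, cfg: TransportConfig) -> np.ndarray:
    """Deterministic expected counts on one panel (real-valued image).

    For each source sub-volume point ``s`` and each hole, the set of photon
    directions that thread the hole is found by projecting the detector-side
    aperture from ``s`` onto the entrance plane and intersecting it with the
    entrance aperture (both axis-aligned squares, and the diverging hole is
    convex, so threading both apertures is necessary and sufficient).  The
    exact solid angle of that intersection gives the pixel's acceptance.
    """
    col, det = panel.collimator, panel.detector
    F, h = panel.focal_len, col.height_h
    d = col.hole_size_d
    n = col.holes_per_side
    off = panel.hole_offsets()
    hx = off[None, :]  # along u -> image columns j
    hy = off[:, None]  # along v -> image rows i

    pts = source_sample_points(source, cfg.source_subsamples)
    local = panel.to_panel(pts)
    emitted = cfg.emitted(source)
    eff = cfg.detection_efficiency
    mu = cfg.attenuation_coeff if cfg.attenuation_coeff is not None else col.attenuation_coeff

    omega = np.zeros((n, n))
    pen = np.zeros((n, n))
    n_used = 0
    for s in local:
        sx, sy, sz = s
        if sz <= F + h + 1e-9:
            continue  # behind or inside the collimator: no geometric path
        n_used += 1
        lam = (F + h - sz) / (F - sz)
        a = lam * d / 2.0
        b = (d / 2.0) * (F + h) / F
        pcx = sx + lam * (hx - sx)
        pcy = sy + lam * (hy - sy)
        ecx = hx * (F + h) / F
        ecy = hy * (F + h) / F
        x1 = np.maximum(pcx - a, ecx - b)
        x2 = np.minimum(pcx + a, ecx + b)
        y1 = np.maximum(pcy - a, ecy - b)
        y2 = np.minimum(pcy + a, ecy + b)
        open_mask = (x2 > x1) & (y2 > y1)
        dz = sz - (F + h)
        om = np.where(
            open_mask,
            _rect_solid_angle(x1 - sx, np.maximum(x1, x2) - sx, y1 - sy, np.maximum(y1, y2) - sy, dz),
            0.0,
        )
        omega += om
        if cfg.septal_penetration and mu > 0:
            # attenuated contribution along the central ray to each blocked hole
            hz = np.broadcast_to(np.full_like(hx + hy, F), (n, n))
            tgt = np.column_stack(
                [np.broadcast_to(hx, (n, n)).ravel(), np.broadcast_to(hy, (n, n)).ravel(), hz.ravel()]
            )
            svec = np.broadcast_to(s, tgt.shape)
            t_ent = (F + h - sz) / (tgt[:, 2] - sz)
            start = svec + t_ent[:, None] * (tgt - svec)
            ell = _tungsten_path(panel, start, tgt, cfg.septal_samples)
            dzf = sz - F
            om_pix = _rect_solid_angle(
                hx - d / 2.0 - sx, hx + d / 2.0 - sx, hy - d / 2.0 - sy, hy + d / 2.0 - sy, dzf
            )
            trans = septal_transmission(ell, mu).reshape(n, n)
            pen += np.where(open_mask, 0.0, om_pix * trans)

    if n_used:
        omega /= n_used
        pen /= n_used
    img = emitted * eff * (omega + pen) / (4.0 * np.pi)
    return img + cfg.ambient_background


def simulate_image(
    panel: Panel,
    source: SourceState,
    cfg: TransportConfig,
    rng: np.random.Generator | None = None,
) -> CountImage:
    """Monte Carlo count image for one panel.

    Emission points are sampled uniformly in the source cylinder; directions
    are importance-sampled onto the collimator entrance apertures (uniform
    hole choice, uniform point in its aperture) with the exact
    ``A cos(theta) / (4 pi r^2)`` weight, so the per-pixel accumulated weight
    is an unbiased estimate of :func:`expected_image`.  The returned counts
    are a Poisson realization of that estimate.
    """
    col, det = panel.collimator, panel.detector
    F, h = panel.focal_len, col.height_h
    d = col.hole_size_d
    n_holes = col.holes_per_side
    off = panel.hole_offsets()
    seed = cfg.rng_seed
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    mu = cfg.attenuation_coeff if cfg.attenuation_coeff is not None else col.attenuation_coeff

    lam = np.zeros((n_holes, n_holes))
    n = cfg.n_photons
    emitted = cfg.emitted(source) * cfg.detection_efficiency
    if n > 0 and emitted > 0:
        chunk = 1 << 19
        scale_e = (F + h) / F  # entrance-aperture magnification
        area = (d * scale_e) ** 2
        m_holes = n_holes * n_holes
        done = 0
        while done < n:
            m = min(chunk, n - done)
            done += m
            # emission points, world -> panel local
            u = rng.random(m)
            phi = rng.random(m) * 2 * np.pi
            r = (source.diameter / 2.0) * np.sqrt(u)
            zc = (rng.random(m) - 0.5) * source.length
            a_ = source.axis
            ref = np.array([1.0, 0.0, 0.0]) if abs(a_[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            e1 = np.cross(a_, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(a_, e1)
            pts = (
                source.center
                + (r * np.cos(phi))[:, None] * e1
                + (r * np.sin(phi))[:, None] * e2
                + zc[:, None] * a_
            )
            s = panel.to_panel(pts)
            ok = s[:, 2] > F + h + 1e-9
            if not np.any(ok):
                continue
            s = s[ok]
            m_ok = s.shape[0]
            kx = rng.integers(0, n_holes, m_ok)
            ky = rng.integers(0, n_holes, m_ok)
            tx = off[kx] * scale_e + (rng.random(m_ok) - 0.5) * d * scale_e
            ty = off[ky] * scale_e + (rng.random(m_ok) - 0.5) * d * scale_e
            tgt = np.column_stack([tx, ty, np.full(m_ok, F + h)])
            vec = tgt - s
            r2 = np.einsum("ij,ij->i", vec, vec)
            cos_t = np.abs(vec[:, 2]) / np.sqrt(r2)
            w = emitted * m_holes * area * cos_t / (4.0 * np.pi * r2) / n
            # continue the ray to the detector-side face
            t_exit = (F - s[:, 2]) / vec[:, 2]
            ex = s[:, 0] + t_exit * vec[:, 0]
            ey = s[:, 1] + t_exit * vec[:, 1]
            inside = (np.abs(ex - off[kx]) <= d / 2.0) & (np.abs(ey - off[ky]) <= d / 2.0)
            np.add.at(lam, (ky[inside], kx[inside]), w[inside])
            if cfg.septal_penetration and mu > 0:
                miss = ~inside
                if np.any(miss):
                    end = np.column_stack([ex[miss], ey[miss], np.full(miss.sum(), F)])
                    ell = _tungsten_path(panel, tgt[miss], end, cfg.septal_samples)
                    trans = np.exp(-mu * ell)
                    jj = np.rint((ex[miss] - off[0]) / col.pitch).astype(int)
                    ii = np.rint((ey[miss] - off[0]) / col.pitch).astype(int)
                    good = (jj >= 0) & (jj < n_holes) & (ii >= 0) & (ii < n_holes) & (trans > 1e-12)
                    np.add.at(lam, (ii[good], jj[good]), (w[miss] * trans)[good])
    lam += cfg.ambient_background
    counts = rng.poisson(lam).astype(np.int64)
    return CountImage(
        counts=counts,
        panel_id=panel.panel_id,
        exposure_time=source.exposure_time,
        rng_seed=seed,
        model_tag="monte-carlo",
    )


def acquire_all(
    layout: SystemLayout, source: SourceState, cfg: TransportConfig
) -> list[CountImage]:
    """One simultaneous acquisition: one Monte Carlo image per panel.

    Per-panel generators are spawned from the master seed with numpy's
    splittable ``SeedSequence``, so the whole acquisition is reproducible and
    each panel's stream is independent.
    """
    children = np.random.SeedSequence(cfg.rng_seed).spawn(len(layout))
    images = []
    for panel, child in zip(layout, children):
        rng = np.random.default_rng(child)
        img = simulate_image(panel, source, cfg, rng=rng)
        img.rng_seed = int(child.generate_state(1)[0])
        images.append(img)
    return images
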