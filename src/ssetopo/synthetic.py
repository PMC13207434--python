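"""Ground-truthed synthetic proteins: ideal-geometry model SSEs plus
detector-like density sticks.

The generator emulates the discrepancies that map-side SSE detectors introduce
at medium resolution and that the incomplete-matching evaluation protocol is
designed around: coordinate noise, end erosion, whole-stick dropout,
fragmentation into two pieces, and point-order reversal.

Model SSEs use standard protein geometry — α-helix Cα spiral of radius
2.3 Å, rise 1.5 Å/residue, 100°/residue twist; β-strands as near-linear
traces with a small alternating zig-zag and 3.3 Å/residue rise.  SSEs are
centered on a cubic grid whose cell size is the configured placement spacing
plus the largest possible SSE extent, which guarantees a comfortable
inter-SSE gap (≥ placement_spacing − a few Å), far larger than both the
training jitter and any realistic stick noise.

Randomness is organized as per-SSE substreams keyed by the SSE id (CRC32),
with a documented fixed draw order inside each substream — corruption
decisions (dropout, fragmentation + split point, reversal) first, then the
noise normals — so toggling one corruption mode does not perturb the draws of
the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .errors import ConfigError
from .sse_io import DensityStick, GroundTruth, ModelSSE

__all__ = ["SimulationConfig", "SimulatedProtein", "generate_model",
           "simulate_sticks", "simulate_protein"]

# canonical backbone geometry (Å, degrees)
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
STRAND_RISE = 3.3
STRAND_ZIGZAG = 0.9

#: stick axis sampling density: ~1 point per this many Å of arc
STICK_POINT_SPACING = 1.5


@dataclass
class SimulationConfig:
    """Study conditions for one simulated protein."""

    n_helices: int = 6
    n_strands: int = 4
    helix_len_range: tuple = (8, 20)
    strand_len_range: tuple = (4, 10)
    placement_spacing: float = 20.0
    noise_sigma: float = 0.0
    erosion_frac: float = 0.0
    drop_prob: float = 0.0
    fragment_prob: float = 0.0
    reversal_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_prob", "fragment_prob", "reversal_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not 0.0 <= self.erosion_frac <= 0.4:
            raise ConfigError("erosion_frac must be in [0, 0.4]")
        for name in ("helix_len_range", "strand_len_range"):
            lo, hi = getattr(self, name)
            if lo < 3 or hi < lo:
                raise ConfigError(f"{name} must be an interval with min >= 3")
        if self.placement_spacing <= 0:
            raise ConfigError("placement_spacing must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulatedProtein:
    """A synthetic protein with its stick detections and full ground truth."""

    model_sses: list
    sticks: list
    truth: GroundTruth
    provenance: dict = field(default_factory=dict)  # stick_id -> source sse_id


def _substream(seed: int, tag: str, sse_id: str) -> np.random.Generator:
    """Independent, reproducible per-SSE stream keyed by the SSE id."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(tag.encode()), zlib.crc32(sse_id.encode())]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion from 4 normals)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _helix_trace(n_res: int) -> np.ndarray:
    t = np.arange(n_res)
    ang = np.deg2rad(HELIX_TURN_DEG) * t
    return np.column_stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * t]
    )


def _strand_trace(n_res: int) -> np.ndarray:
    t = np.arange(n_res)
    zig = STRAND_ZIGZAG * np.where(t % 2 == 0, 1.0, -1.0)
    return np.column_stack([zig, np.zeros(n_res), STRAND_RISE * t])


def _max_extent(config: SimulationConfig) -> float:
    h = (config.helix_len_range[1] - 1) * HELIX_RISE + 2 * HELIX_RADIUS
    s = (config.strand_len_range[1] - 1) * STRAND_RISE + 2 * STRAND_ZIGZAG
    return max(h, s)


def generate_model(config: SimulationConfig) -> list:
    """Deterministically generate the model-side SSE set of one protein.

    Helices H1..Hn first, then strands S1..Sn, each randomly oriented and
    centered on its own cell of a cubic grid (see module docstring for the
    separation guarantee).  Residue numbers are sequential along chain A with
    a 5-residue gap between consecutive SSEs.
    """
    total = config.n_helices + config.n_strands
    if total == 0:
        raise ConfigError("zero SSEs requested")
    cell = config.placement_spacing + _max_extent(config)
    side = int(np.ceil(total ** (1.0 / 3.0)))

    specs = [("helix", f"H{i + 1}") for i in range(config.n_helices)]
    specs += [("strand", f"S{i + 1}") for i in range(config.n_strands)]

    # assign SSEs to a seeded permutation of the full side^3 grid so every
    # coordinate axis carries class-to-class variance (a type-blocked raster
    # layout would leave whole axes nearly constant within a type, which is
    # both unrealistic and degenerate under feature standardization)
    placement_rng = _substream(config.seed, "placement", "protein")
    cells = placement_rng.permutation(side ** 3)[:total]

    sses = []
    next_res = 1
    for idx, (sse_type, sse_id) in enumerate(specs):
        rng = _substream(config.seed, "model", sse_id)
        # draw order: residue count, orientation quaternion, center jitter
        if sse_type == "helix":
            lo, hi = config.helix_len_range
        else:
            lo, hi = config.strand_len_range
        n_res = int(rng.integers(lo, hi + 1))
        rot = _random_rotation(rng)
        jitter = rng.uniform(-0.05 * cell, 0.05 * cell, size=3)
        trace = _helix_trace(n_res) if sse_type == "helix" else _strand_trace(n_res)
        trace = trace - trace.mean(axis=0)
        ci = int(cells[idx])
        center = cell * np.array(
            [ci % side, (ci // side) % side, ci // (side * side)], dtype=float
        ) + jitter
        coords = trace @ rot.T + center
        sses.append(
            ModelSSE(
                sse_id=sse_id,
                sse_type=sse_type,
                chain_id="A",
                residue_range=(next_res, next_res + n_res - 1),
                calpha_coords=coords,
            )
        )
        next_res += n_res + 5
    return sses


def simulate_sticks(model_sses, config: SimulationConfig) -> SimulatedProtein:
    """Derive detector-like sticks from model SSEs with seeded corruptions.

    Per SSE, in a fixed order: dropout decision; resampling of the Cα trace
    to ~1 axis point per 1.5 Å; end erosion; additive Gaussian noise;
    fragmentation at a uniform interior point (at most two children — the
    larger child carries the ground-truth pair, the smaller one becomes an
    unmatched stick); point-order reversal (truth direction −1).
    """
    sticks = []
    pairs = []
    unmatched_sses = []
    unmatched_sticks = []
    provenance = {}
    counter = 0

    for sse in model_sses:
        rng = _substream(config.seed, "stick", sse.sse_id)
        # fixed draw order: dropout, fragmentation decision + split point,
        # reversal — then noise normals
        u_drop = rng.uniform()
        u_frag = rng.uniform()
        u_split = rng.uniform()
        u_rev = rng.uniform()

        if u_drop < config.drop_prob:
            unmatched_sses.append(sse.sse_id)
            continue

        arc = geometry.polyline_length(sse.calpha_coords)
        n_pts = max(2, int(round(arc / STICK_POINT_SPACING)) + 1)
        pts = geometry.resample_polyline(sse.calpha_coords, n_pts)

        erode = int(np.floor(config.erosion_frac * n_pts))
        while n_pts - 2 * erode < 2:
            erode -= 1
        if erode > 0:
            pts = pts[erode:n_pts - erode]

        # normals are drawn unconditionally and scaled by sigma, so setting
        # sigma to 0 does not shift the other draws
        pts = pts + config.noise_sigma * rng.normal(0.0, 1.0, size=pts.shape)

        fragment = u_frag < config.fragment_prob and len(pts) >= 4
        reverse = u_rev < config.reversal_prob
        direction = -1 if reverse else +1

        if fragment:
            split = 2 + int(u_split * (len(pts) - 3))  # split in [2, len-2]
            children = [pts[:split], pts[split:]]
            # larger child (more points; tie -> first) carries the truth pair
            main = 0 if len(children[0]) >= len(children[1]) else 1
            ids = []
            for child in children:
                counter += 1
                ids.append(f"V{counter}")
                sticks.append(
                    DensityStick(
                        stick_id=ids[-1],
                        sse_type=sse.sse_type,
                        axis_points=child[::-1] if reverse else child,
                    )
                )
                provenance[ids[-1]] = sse.sse_id
            pairs.append((sse.sse_id, ids[main], direction))
            unmatched_sticks.append(ids[1 - main])
        else:
            counter += 1
            sid = f"V{counter}"
            sticks.append(
                DensityStick(
                    stick_id=sid,
                    sse_type=sse.sse_type,
                    axis_points=pts[::-1] if reverse else pts,
                )
            )
            provenance[sid] = sse.sse_id
            pairs.append((sse.sse_id, sid, direction))

    truth = GroundTruth(
        pairs=pairs,
        unmatched_sses=unmatched_sses,
        unmatched_sticks=unmatched_sticks,
    )
    return SimulatedProtein(
        model_sses=list(model_sses), sticks=sticks, truth=truth,
        provenance=provenance,
    )


def simulate_protein(config: SimulationConfig) -> SimulatedProtein:
    """Convenience: generate the model and its sticks in one call."""
    return simulate_sticks(generate_model(config), config)
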