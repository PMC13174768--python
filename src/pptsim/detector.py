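"""Idealized cylindrical PET ring: singles detection and coincidence sorting.

Crystals are perfect absorbers on the front face of a cylinder of the
configured radius; each incident photon inside the axial extent is
accepted with the configured efficiency, its energy and time blurred with
Gaussian resolutions, and assigned to the nearest crystal center.  Prompt
coincidences are pairs of hits inside the coincidence time window with
both energies in the energy window; windows containing more than two
hits are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transport import C_MM_PER_NS, EventLog

__all__ = [
    "DetectorRing",
    "Singles",
    "CoincidenceList",
    "detect_singles",
    "sort_coincidences",
    "detect_coincidences",
    "CLINICAL_RING",
    "PRECLINICAL_RING",
]

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


@dataclass(frozen=True)
class DetectorRing:
    """Geometry and response of the cylindrical detector ring.

    ``timing_resolution_fwhm_ps`` is the coincidence resolving time; each
    single is blurred with sigma = CRT / (2.355 * sqrt(2)).  A value of 0
    disables timing blur (and TOF information is then exact).
    """

    radius_mm: float = 410.0
    axial_length_mm: float = 263.0
    pitch_trans_mm: float = 3.2
    pitch_axial_mm: float = 3.2
    energy_resolution_fwhm: float = 0.10
    energy_window_kev: tuple[float, float] = (435.0, 585.0)
    coincidence_window_ns: float = 4.0
    timing_resolution_fwhm_ps: float = 214.0
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.energy_window_kev
        if lo >= hi:
            raise ValueError("energy window bounds must be ordered")
        if self.coincidence_window_ns <= 0:
            raise ValueError("coincidence window must be positive")
        if not 0 <= self.efficiency <= 1:
            raise ValueError("efficiency must be in [0, 1]")

    @property
    def n_crystals_trans(self) -> int:
        return max(1, int(round(2 * np.pi * self.radius_mm / self.pitch_trans_mm)))

    @property
    def n_crystals_axial(self) -> int:
        return max(1, int(round(self.axial_length_mm / self.pitch_axial_mm)))

    def crystal_center(self, i_trans, i_axial):
        """World coordinates (mm) of crystal centers."""
        dphi = 2 * np.pi / self.n_crystals_trans
        phi = (np.asarray(i_trans) + 0.5) * dphi
        z = -0.5 * self.axial_length_mm + (np.asarray(i_axial) + 0.5) * self.pitch_axial_mm
        return np.stack(
            [
                self.radius_mm * np.cos(phi),
                self.radius_mm * np.sin(phi),
                z * np.ones_like(phi),
            ],
            axis=-1,
        )


# presets loosely following the two scanner classes in the study
CLINICAL_RING = DetectorRing()
PRECLINICAL_RING = DetectorRing(
    radius_mm=80.0,
    axial_length_mm=100.0,
    pitch_trans_mm=1.12,
    pitch_axial_mm=1.12,
    timing_resolution_fwhm_ps=0.0,
)


@dataclass
class Singles:
    """Columnar list of detected single hits, time-ordered or not."""

    crystal_trans: np.ndarray
    crystal_axial: np.ndarray
    position: np.ndarray  # crystal centers, mm
    energy_kev: np.ndarray
    time_ns: np.ndarray
    event_id: np.ndarray
    n_skipped_outside_bore: int = 0

    def __len__(self) -> int:
        return len(self.time_ns)


@dataclass
class CoincidenceList:
    """Prompt coincidences: two crystal hits with energies, times and dt."""

    crystal1: np.ndarray  # (n, 2) trans/axial indices
    crystal2: np.ndarray
    pos1: np.ndarray  # (n, 3) crystal centers, mm
    pos2: np.ndarray
    energy1_kev: np.ndarray
    energy2_kev: np.ndarray
    time1_ns: np.ndarray
    time2_ns: np.ndarray
    event_id1: np.ndarray
    event_id2: np.ndarray
    ring: DetectorRing = field(default_factory=DetectorRing)

    @property
    def dt_ns(self) -> np.ndarray:
        """TOF time difference t1 - t2."""
        return self.time1_ns - self.time2_ns

    def __len__(self) -> int:
        return len(self.time1_ns)

    def save_listmode(self, path) -> None:
        """Write a delimited-text list-mode file with a geometry header."""
        header = (
            f"# pptsim list-mode coincidences\n"
            f"# ring radius_mm={self.ring.radius_mm} "
            f"axial_mm={self.ring.axial_length_mm} "
            f"pitch_trans_mm={self.ring.pitch_trans_mm} "
            f"pitch_axial_mm={self.ring.pitch_axial_mm}\n"
            "# it1 ia1 it2 ia2 x1 y1 z1 x2 y2 z2 e1_kev e2_kev t1_ns t2_ns"
        )
        data = np.column_stack(
            [
                self.crystal1,
                self.crystal2,
                self.pos1,
                self.pos2,
                self.energy1_kev,
                self.energy2_kev,
                self.time1_ns,
                self.time2_ns,
            ]
        )
        np.savetxt(path, data, header=header, comments="")

    @classmethod
    def load_listmode(cls, path, ring: DetectorRing | None = None):
        with open(path) as f:
            lines = [ln for ln in f if ln.strip()]
        meta = {}
        body = []
        for ln in lines:
            if ln.startswith("#"):
                for tok in ln[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=")
                        meta[k] = float(v)
            else:
                body.append([float(x) for x in ln.split()])
        if ring is None:
            ring = DetectorRing(
                radius_mm=meta.get("radius_mm", 410.0),
                axial_length_mm=meta.get("axial_mm", 263.0),
                pitch_trans_mm=meta.get("pitch_trans_mm", 3.2),
                pitch_axial_mm=meta.get("pitch_axial_mm", 3.2),
            )
        arr = np.asarray(body, dtype=float).reshape(len(body), 14)
        n = len(arr)
        return cls(
            crystal1=arr[:, 0:2].astype(int),
            crystal2=arr[:, 2:4].astype(int),
            pos1=arr[:, 4:7],
            pos2=arr[:, 7:10],
            energy1_kev=arr[:, 10],
            energy2_kev=arr[:, 11],
            time1_ns=arr[:, 12],
            time2_ns=arr[:, 13],
            event_id1=np.arange(n),
            event_id2=np.arange(n),
            ring=ring,
        )


def detect_singles(
    origins: np.ndarray,
    directions: np.ndarray,
    times_ns: np.ndarray,
    ring: DetectorRing,
    rng: np.random.Generator,
    energies_mev: np.ndarray | None = None,
    event_ids: np.ndarray | None = None,
) -> Singles:
    """Project photons onto the ring and record blurred hits.

    Photons whose origin lies outside the bore are skipped and counted;
    photons that miss the cylinder axially (or travel parallel to the
    axis) are lost.  Hits are assigned to the nearest crystal center.
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    t = np.atleast_1d(np.asarray(times_ns, dtype=float))
    n = len(t)
    e = (
        np.full(n, 0.511)
        if energies_mev is None
        else np.atleast_1d(np.asarray(energies_mev, dtype=float))
    )
    ids = np.arange(n) if event_ids is None else np.asarray(event_ids)

    r2 = o[:, 0] ** 2 + o[:, 1] ** 2
    inside_bore = r2 < ring.radius_mm**2
    n_skipped = int(np.sum(~inside_bore))

    a = d[:, 0] ** 2 + d[:, 1] ** 2
    ok = inside_bore & (a > 1e-12)
    # forward intersection of the ray with the cylinder |xy| = R
    b = o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1]
    disc = np.where(ok, b**2 - a * (r2 - ring.radius_mm**2), 0.0)
    s = np.where(ok, (-b + np.sqrt(np.maximum(disc, 0.0))) / np.maximum(a, 1e-12), 0.0)
    hit = o + s[:, None] * d
    ok &= np.abs(hit[:, 2]) <= 0.5 * ring.axial_length_mm
    if ring.efficiency < 1.0:
        ok &= rng.random(n) < ring.efficiency

    idx = np.flatnonzero(ok)
    hit = hit[idx]
    dphi = 2 * np.pi / ring.n_crystals_trans
    phi = np.mod(np.arctan2(hit[:, 1], hit[:, 0]), 2 * np.pi)
    i_trans = np.floor(phi / dphi).astype(int) % ring.n_crystals_trans
    zrel = hit[:, 2] + 0.5 * ring.axial_length_mm
    i_ax = np.clip(
        np.floor(zrel / ring.pitch_axial_mm).astype(int), 0, ring.n_crystals_axial - 1
    )
    centers = ring.crystal_center(i_trans, i_ax)

    flight = np.linalg.norm(hit - o[idx], axis=1) / C_MM_PER_NS
    t_hit = t[idx] + flight
    if ring.timing_resolution_fwhm_ps > 0:
        sigma_ns = ring.timing_resolution_fwhm_ps * FWHM_TO_SIGMA / np.sqrt(2) / 1000.0
        t_hit = t_hit + rng.normal(0.0, sigma_ns, len(idx))
    e_kev = e[idx] * 1000.0
    if ring.energy_resolution_fwhm > 0:
        e_kev = e_kev + rng.normal(0.0, ring.energy_resolution_fwhm * FWHM_TO_SIGMA * e_kev)

    return Singles(
        crystal_trans=i_trans,
        crystal_axial=i_ax,
        position=centers,
        energy_kev=e_kev,
        time_ns=t_hit,
        event_id=ids[idx],
        n_skipped_outside_bore=n_skipped,
    )


def sort_coincidences(singles: Singles, ring: DetectorRing) -> CoincidenceList:
    """Group time-sorted singles into prompt coincidences.

    A window opens at each otherwise-unassigned hit; all hits within the
    coincidence window of the opener belong to the group.  Groups of
    exactly two hits with both energies inside the energy window become
    coincidences; larger groups are discarded (multiple rejection).
    """
    order = np.argsort(singles.time_ns, kind="stable")
    t = singles.time_ns[order]
    tau = ring.coincidence_window_ns
    lo, hi = ring.energy_window_kev
    pairs: list[tuple[int, int]] = []
    i, n = 0, len(t)
    while i < n:
        j = i + 1
        while j < n and t[j] - t[i] <= tau:
            j += 1
        if j - i == 2:
            pairs.append((order[i], order[i + 1]))
        i = j
    if pairs:
        p = np.asarray(pairs)
        e1 = singles.energy_kev[p[:, 0]]
        e2 = singles.energy_kev[p[:, 1]]
        keep = (e1 >= lo) & (e1 <= hi) & (e2 >= lo) & (e2 <= hi)
        p = p[keep]
    else:
        p = np.zeros((0, 2), dtype=int)
    i1, i2 = p[:, 0], p[:, 1]
    return CoincidenceList(
        crystal1=np.column_stack([singles.crystal_trans[i1], singles.crystal_axial[i1]]),
        crystal2=np.column_stack([singles.crystal_trans[i2], singles.crystal_axial[i2]]),
        pos1=singles.position[i1],
        pos2=singles.position[i2],
        energy1_kev=singles.energy_kev[i1],
        energy2_kev=singles.energy_kev[i2],
        time1_ns=singles.time_ns[i1],
        time2_ns=singles.time_ns[i2],
        event_id1=singles.event_id[i1],
        event_id2=singles.event_id[i2],
        ring=ring,
    )


def detect_coincidences(
    log: EventLog,
    ring: DetectorRing,
    rng: np.random.Generator,
    history_spacing_ns: float = 1e5,
) -> CoincidenceList:
    """Run the acquisition chain on a simulation's escaped photon pairs.

    Each annihilation is offset in absolute time by its index times
    ``history_spacing_ns`` so that distinct histories never overlap in a
    coincidence window (randoms are not simulated by default).
    """
    if log.phot_ann_index is None:
        raise ValueError(
            "event log has no tracked annihilation photons; rerun with "
            "track_annihilation_photons=True"
        )
    esc_pair = log.phot_escaped1 & log.phot_escaped2
    idx = np.flatnonzero(esc_pair)  # photon rows parallel the annihilation table
    origins = np.vstack([log.ann_r_a[idx], log.ann_r_a[idx]])
    dirs = np.vstack([log.phot_dir1[idx], log.phot_dir2[idx]])
    t0 = log.ann_time[idx] + np.arange(len(idx)) * history_spacing_ns
    times = np.concatenate([t0, t0])
    ids = np.concatenate([log.ann_history[idx], log.ann_history[idx]])
    singles = detect_singles(origins, dirs, times, ring, rng, event_ids=ids)
    return sort_coincidences(singles, ring)
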