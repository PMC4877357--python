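"""Landmark I/O and Procrustes machinery.

Reads 2-D landmark configurations (TPS or long CSV), estimates missing
bilateral points by reflection across the specimen's symmetry axis, runs
generalized Procrustes analysis (GPA) with bending-energy sliding of
semilandmarks, extracts the symmetric component of shape variation for
object-symmetric structures, and removes allometry by regressing shape on
centroid size.

Point roles
-----------
``landmark``      anatomically homologous point, fixed during sliding.
``semilandmark``  point on a curve without exact correspondence; slides
                  along the local tangent to minimise bending energy.
``helper``        semilandmark used only to anchor the superimposition;
                  participates in alignment but is dropped from the shape
                  variables afterwards.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

VALID_ROLES = ("landmark", "semilandmark", "helper")

#: convergence tolerance on RMS change of the consensus between iterations
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100


class LandmarkFormatError(ValueError):
    """Malformed landmark file (ragged configurations, bad header...)."""


class LandmarkConfigError(ValueError):
    """Inconsistent dataset configuration (roles, pairing, curves)."""


@dataclass
class LandmarkDataset:
    """Raw specimen point configurations plus point metadata.

    coords has shape (n_specimens, n_points, 2). ``curves`` are ordered
    index chains giving each semilandmark its sliding neighbours.
    ``pairing`` lists (left, right) index pairs for object-symmetric
    structures; ``midline`` the indices on the symmetry axis.
    """

    specimen_ids: list
    coords: np.ndarray
    point_roles: list
    curves: list = field(default_factory=list)
    pairing: list = field(default_factory=list)
    midline: list = field(default_factory=list)
    missing_mask: np.ndarray | None = None
    group_labels: list | None = None
    imputed_mask: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise LandmarkFormatError(
                f"coords must be (n, k, 2), got {self.coords.shape}")
        n, k, _ = self.coords.shape
        if len(self.specimen_ids) != n:
            raise LandmarkFormatError("specimen_ids length mismatch")
        if len(self.point_roles) != k:
            raise LandmarkConfigError(
                f"{k} points but {len(self.point_roles)} roles")
        for r in self.point_roles:
            if r not in VALID_ROLES:
                raise LandmarkConfigError(f"unknown point role {r!r}")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.coords).all(axis=2)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        paired = {i for pr in self.pairing for i in pr}
        if paired & set(self.midline):
            raise LandmarkConfigError("paired indices overlap midline indices")
        in_curve = [i for c in self.curves for i in c]
        for i, role in enumerate(self.point_roles):
            if role == "semilandmark" and in_curve.count(i) != 1:
                raise LandmarkConfigError(
                    f"semilandmark {i} must appear in exactly one curve")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]


@dataclass
class AlignedShapes:
    """Procrustes-superimposed tangent-space coordinates.

    ``proc_coords`` has shape (n, k_retained, 2) — helper points removed.
    Centroid sizes are in the units of the input coordinates.
    """

    specimen_ids: list
    proc_coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    retained_roles: list
    group_labels: list | None = None
    converged: bool = True
    n_iter: int = 0

    def as_matrix(self) -> np.ndarray:
        """Flatten to an (n, 2k) shape-variable matrix (x1,y1,x2,y2,...)."""
        n = self.proc_coords.shape[0]
        return self.proc_coords.reshape(n, -1)


@dataclass
class ShapeResiduals:
    """Allometry-corrected shape variables.

    residuals are regression residuals with the consensus added back so
    they remain interpretable as shapes; they are exactly uncorrelated
    with the (centered) size vector used in the regression.
    """

    specimen_ids: list
    residuals: np.ndarray
    regression_vector: np.ndarray
    percent_predicted: float
    sizes: np.ndarray
    group_labels: list | None = None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_landmarks(path, fmt: str, roles_spec, curves=None, pairing=None,
                   midline=None, group_labels=None) -> LandmarkDataset:
    """Read a TPS or long-format CSV landmark file.

    ``roles_spec`` is a sequence of point roles (one per point). TPS
    SCALE= factors are applied; TPS indices are 1-based on disk and
    0-based in memory. CSV long format columns: specimen, point, x, y;
    empty/NA cells mark missing points.
    """
    if fmt == "tps":
        ids, coords = _read_tps(path)
    elif fmt == "csv":
        ids, coords = _read_long_csv(path)
    else:
        raise LandmarkConfigError(f"unknown format {fmt!r}")
    lens = {c.shape[0] for c in coords}
    if len(lens) > 1:
        bad = [i for i, c in zip(ids, coords)
               if c.shape[0] != coords[0].shape[0]]
        raise LandmarkFormatError(
            f"ragged configurations: specimens {bad} differ in point count")
    arr = np.stack(coords)
    return LandmarkDataset(
        specimen_ids=list(ids), coords=arr, point_roles=list(roles_spec),
        curves=list(curves or []), pairing=list(pairing or []),
        midline=list(midline or []), group_labels=group_labels)


def _read_tps(path):
    ids, coords = [], []
    cur, scale, cur_id = None, None, None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.upper()
            if key == "LM":
                if cur is not None:
                    _flush_tps(ids, coords, cur, scale, cur_id)
                cur, scale, cur_id = [], None, None
            elif key == "ID":
                cur_id = val.strip()
            elif key == "SCALE":
                scale = float(val)
            elif key in ("IMAGE", "CURVES", "POINTS"):
                continue
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise LandmarkFormatError(f"bad TPS coordinate line: {line!r}")
                cur.append([float(parts[0]), float(parts[1])])
    if cur is not None:
        _flush_tps(ids, coords, cur, scale, cur_id)
    if not coords:
        raise LandmarkFormatError(f"no configurations found in {path}")
    return ids, coords


def _flush_tps(ids, coords, cur, scale, cur_id):
    arr = np.asarray(cur, dtype=float)
    if scale is not None:
        arr = arr * scale
    ids.append(cur_id if cur_id is not None else str(len(ids)))
    coords.append(arr)


def _read_long_csv(path):
    rows = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            sid = rec["specimen"]
            idx = int(rec["point"])
            def _val(s):
                s = (s or "").strip()
                return np.nan if s in ("", "NA", "NaN", "nan") else float(s)
            rows.setdefault(sid, {})[idx] = (_val(rec["x"]), _val(rec["y"]))
    ids = list(rows)
    k = max(max(d) for d in rows.values()) + 1
    coords = []
    for sid in ids:
        arr = np.full((k, 2), np.nan)
        for idx, xy in rows[sid].items():
            arr[idx] = xy
        coords.append(arr)
    return ids, coords


def read_sliders(path):
    """Read a three-column slider (neighbour-triplet) file, tpsUtil dialect.

    Returns curves as [before, slider, after] 0-based triplets (file is
    1-based). Lines starting with non-digits are skipped as headers.
    """
    curves = []
    with open(path) as fh:
        for line in fh:
            parts = line.replace(",", " ").split()
            if len(parts) != 3 or not parts[0].lstrip("-").isdigit():
                continue
            curves.append([int(p) - 1 for p in parts])
    return curves


def write_aligned_csv(aligned: AlignedShapes, path):
    """Export aligned shapes as wide CSV (one row per specimen)."""
    mat = aligned.as_matrix()
    k = aligned.proc_coords.shape[1]
    header = ["specimen", "centroid_size"] + [
        f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for sid, cs, row in zip(aligned.specimen_ids,
                                aligned.centroid_sizes, mat):
            w.writerow([sid, cs] + list(row))


# ---------------------------------------------------------------------------
# Missing-point estimation by reflection
# ---------------------------------------------------------------------------

class UnrecoverableSpecimenError(ValueError):
    pass


def estimate_missing_by_reflection(ds: LandmarkDataset) -> LandmarkDataset:
    """Impute missing bilateral points as mirror images of their pair.

    The specimen's symmetry axis is the principal axis of its midline
    points together with the midpoints of its complete pairs; a missing
    point is replaced by the reflection of its (present) counterpart
    across that axis. Fails if both members of a pair are missing.
    """
    if not ds.pairing:
        raise LandmarkConfigError("pairing required for reflection imputation")
    coords = ds.coords.copy()
    missing = ds.missing_mask.copy()
    imputed = np.zeros_like(missing)
    pair_of = {}
    for l, r in ds.pairing:
        pair_of[l], pair_of[r] = r, l
    for s in range(ds.n_specimens):
        miss = np.flatnonzero(missing[s])
        if miss.size == 0:
            continue
        bad = [(l, r) for l, r in ds.pairing
               if missing[s, l] and missing[s, r]]
        if bad:
            raise UnrecoverableSpecimenError(
                f"specimen {ds.specimen_ids[s]}: both members missing "
                f"for pairs {bad}")
        unpaired = [i for i in miss if i not in pair_of]
        if unpaired:
            raise UnrecoverableSpecimenError(
                f"specimen {ds.specimen_ids[s]}: missing unpaired "
                f"points {unpaired}")
        axis_pts = [coords[s, i] for i in ds.midline if not missing[s, i]]
        for l, r in ds.pairing:
            if not missing[s, l] and not missing[s, r]:
                axis_pts.append((coords[s, l] + coords[s, r]) / 2.0)
        if len(axis_pts) < 2:
            raise UnrecoverableSpecimenError(
                f"specimen {ds.specimen_ids[s]}: fewer than 2 points "
                "available to fit a symmetry axis")
        axis_pts = np.asarray(axis_pts)
        center = axis_pts.mean(axis=0)
        u, sv, vt = np.linalg.svd(axis_pts - center, full_matrices=False)
        d = vt[0]  # principal axis direction
        H = 2.0 * np.outer(d, d) - np.eye(2)  # reflection across the axis
        for i in miss:
            j = pair_of[i]
            coords[s, i] = center + H @ (coords[s, j] - center)
            imputed[s, i] = True
            missing[s, i] = False
    return replace(ds, coords=coords, missing_mask=missing,
                   imputed_mask=imputed)


# ---------------------------------------------------------------------------
# GPA with bending-energy sliding
# ---------------------------------------------------------------------------

def centroid_size(config: np.ndarray) -> float:
    c = config - config.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _optimal_rotation(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) of x onto ref, both centered."""
    m = ref.T @ x
    u, s, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, d])
    return (u @ corr @ vt).T


def bending_energy_matrix(ref: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending energy matrix of a 2-D reference.

    Returns the k x k upper-left block of the inverse of the TPS system
    matrix; the bending energy of a target (x, y) relative to ref is
    x'Lx + y'Ly.
    """
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0) / 2.0  # r^2 log r
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.pinv(L)
    Le = Linv[:k, :k]
    return (Le + Le.T) / 2.0


def total_bending_energy(config: np.ndarray, ref: np.ndarray,
                         be: np.ndarray | None = None) -> float:
    if be is None:
        be = bending_energy_matrix(ref)
    return float(config[:, 0] @ be @ config[:, 0]
                 + config[:, 1] @ be @ config[:, 1])


def _slide_one(config: np.ndarray, be2: np.ndarray, sliders: np.ndarray,
               tangents: np.ndarray) -> np.ndarray:
    """Move sliders along their tangents to minimise bending energy.

    be2 is block-diag(L, L) for stacked (x; y) coordinates. Solves the
    quadratic minimisation in closed form.
    """
    k = config.shape[0]
    s = len(sliders)
    U = np.zeros((2 * k, s))
    U[sliders, np.arange(s)] = tangents[:, 0]
    U[k + sliders, np.arange(s)] = tangents[:, 1]
    v0 = np.concatenate([config[:, 0], config[:, 1]])
    A = U.T @ be2 @ U
    rhs = -(U.T @ be2 @ v0)
    lam, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    out = config.copy()
    out[sliders, 0] += lam * tangents[:, 0]
    out[sliders, 1] += lam * tangents[:, 1]
    return out


def _tangent_directions(config: np.ndarray, curves, sliders):
    """Unit tangent at each slider from its curve neighbours (chord)."""
    neigh = {}
    for chain in curves:
        for pos in range(1, len(chain) - 1):
            neigh[chain[pos]] = (chain[pos - 1], chain[pos + 1])
    t = np.zeros((len(sliders), 2))
    for j, i in enumerate(sliders):
        a, b = neigh[i]
        v = config[b] - config[a]
        nrm = np.linalg.norm(v)
        t[j] = v / nrm if nrm > 0 else np.array([1.0, 0.0])
    return t


def gpa_with_sliding(ds: LandmarkDataset, slide_criterion: str = "bending_energy",
                     tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                     drop_helpers: bool = True) -> AlignedShapes:
    """Generalized Procrustes superimposition with semilandmark sliding.

    Iteratively centers, scales to unit centroid size, rotates to the
    consensus, and slides points flagged ``semilandmark`` along their
    curve tangents so as to minimise thin-plate-spline bending energy
    against the consensus. Helper points take part in the alignment but
    are removed from the returned shape variables. Coordinates are
    orthogonally projected to the tangent space at the consensus.
    """
    if slide_criterion != "bending_energy":
        raise LandmarkConfigError(
            f"unsupported sliding criterion {slide_criterion!r}")
    if ds.missing_mask is not None and ds.missing_mask.any():
        raise LandmarkConfigError(
            "missing points present; run estimate_missing_by_reflection first")
    X = ds.coords.copy()
    n, k, _ = X.shape
    cs = np.array([centroid_size(x) for x in X])
    if np.any(cs <= 0):
        raise LandmarkConfigError("degenerate specimen with zero centroid size")
    X = X - X.mean(axis=1, keepdims=True)
    X = X / cs[:, None, None]

    sliders = np.array([i for i, r in enumerate(ds.point_roles)
                        if r == "semilandmark"], dtype=int)
    do_slide = sliders.size > 0 and bool(ds.curves)

    ref = X[0] / np.linalg.norm(X[0])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            R = _optimal_rotation(X[i], ref)
            X[i] = X[i] @ R
        if do_slide:
            be = bending_energy_matrix(ref)
            be2 = np.zeros((2 * k, 2 * k))
            be2[:k, :k] = be
            be2[k:, k:] = be
            for i in range(n):
                t = _tangent_directions(X[i], ds.curves, sliders)
                X[i] = _slide_one(X[i], be2, sliders, t)
                X[i] = X[i] - X[i].mean(axis=0)
                X[i] = X[i] / np.linalg.norm(X[i])
                R = _optimal_rotation(X[i], ref)
                X[i] = X[i] @ R
        new_ref = X.mean(axis=0)
        new_ref = new_ref - new_ref.mean(axis=0)
        new_ref = new_ref / np.linalg.norm(new_ref)
        delta = np.sqrt(((new_ref - ref) ** 2).mean())
        ref = new_ref
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations "
                      f"(last consensus RMS change {delta:.2e})")

    # orthogonal projection onto the tangent space at the consensus
    c = ref.reshape(-1)
    flat = X.reshape(n, -1)
    flat = flat - np.outer(flat @ c - 1.0, c)
    X = flat.reshape(n, k, 2)

    keep = [i for i, r in enumerate(ds.point_roles)
            if not (drop_helpers and r == "helper")]
    retained_roles = [ds.point_roles[i] for i in keep]
    return AlignedShapes(
        specimen_ids=list(ds.specimen_ids),
        proc_coords=X[:, keep, :],
        centroid_sizes=cs,
        consensus=ref[keep, :],
        retained_roles=retained_roles,
        group_labels=list(ds.group_labels) if ds.group_labels else None,
        converged=converged, n_iter=it)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations."""
    def prep(x):
        x = x - x.mean(axis=0)
        return x / np.linalg.norm(x)
    a, b = prep(np.asarray(a, float)), prep(np.asarray(b, float))
    R = _optimal_rotation(b, a)
    return float(np.linalg.norm(a - b @ R))


# ---------------------------------------------------------------------------
# Symmetric component (object symmetry)
# ---------------------------------------------------------------------------

def _reflect_relabel(coords: np.ndarray, pairing, k: int) -> np.ndarray:
    """Mirror a configuration (negate x) and swap left/right labels."""
    out = coords.copy()
    out[:, 0] = -out[:, 0]
    perm = np.arange(k)
    for l, r in pairing:
        perm[l], perm[r] = r, l
    return out[perm]


def symmetric_component(ds: LandmarkDataset, tol: float = DEFAULT_TOL,
                        max_iter: int = DEFAULT_MAX_ITER) -> AlignedShapes:
    """Symmetric component of shape variation for object symmetry.

    Each configuration is paired with its reflected-and-relabeled copy;
    originals and copies enter a joint GPA (with sliding if curves are
    defined) and the symmetric component of a specimen is the average of
    its two aligned copies.
    """
    if not ds.pairing:
        raise LandmarkConfigError("pairing required for symmetric component")
    if ds.missing_mask is not None and ds.missing_mask.any():
        raise LandmarkConfigError("missing points present")
    n, k = ds.n_specimens, ds.n_points
    refl = np.stack([_reflect_relabel(ds.coords[i], ds.pairing, k)
                     for i in range(n)])
    doubled = replace(
        ds,
        specimen_ids=list(ds.specimen_ids) + [f"{s}~refl" for s in ds.specimen_ids],
        coords=np.concatenate([ds.coords, refl]),
        missing_mask=np.zeros((2 * n, k), dtype=bool),
        group_labels=(list(ds.group_labels) * 2 if ds.group_labels else None),
        imputed_mask=None)
    aligned = gpa_with_sliding(doubled, tol=tol, max_iter=max_iter,
                               drop_helpers=False)
    sym = (aligned.proc_coords[:n] + aligned.proc_coords[n:]) / 2.0
    keep = [i for i, r in enumerate(ds.point_roles) if r != "helper"]
    cons = sym.mean(axis=0)
    return AlignedShapes(
        specimen_ids=list(ds.specimen_ids),
        proc_coords=sym[:, keep, :],
        centroid_sizes=aligned.centroid_sizes[:n],
        consensus=cons[keep, :],
        retained_roles=[ds.point_roles[i] for i in keep],
        group_labels=list(ds.group_labels) if ds.group_labels else None,
        converged=aligned.converged, n_iter=aligned.n_iter)


# ---------------------------------------------------------------------------
# Allometry correction
# ---------------------------------------------------------------------------

def allometry_correct(aligned: AlignedShapes, size_source: str = "own_centroid_size",
                      external_sizes: np.ndarray | None = None,
                      log_size: bool = False) -> ShapeResiduals:
    """Regress shape variables on centroid size; return residual shapes.

    With ``size_source='external_size_vector'`` the shape block (e.g.
    pharyngeal jaw) is regressed on an externally supplied size (e.g.
    body centroid size). The regression pools all specimens. Residuals
    get the mean shape added back; percent_predicted is the share (%) of
    total shape variance explained by size.
    """
    Y = aligned.as_matrix()
    if size_source == "own_centroid_size":
        sizes = np.asarray(aligned.centroid_sizes, dtype=float)
    elif size_source == "external_size_vector":
        if external_sizes is None:
            raise ValueError("external_sizes required")
        sizes = np.asarray(external_sizes, dtype=float)
    else:
        raise ValueError(f"unknown size_source {size_source!r}")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be strictly positive")
    x = np.log(sizes) if log_size else sizes.copy()
    xc = x - x.mean()
    mean_shape = Y.mean(axis=0)
    Yc = Y - mean_shape
    ss_x = float(xc @ xc)
    if ss_x <= 1e-14 * len(x):
        warnings.warn("zero size variance; allometry regression skipped")
        return ShapeResiduals(list(aligned.specimen_ids), Yc + mean_shape,
                              np.zeros(Y.shape[1]), 0.0, sizes,
                              aligned.group_labels)
    slope = (xc @ Yc) / ss_x
    pred = np.outer(xc, slope)
    resid = Yc - pred
    ss_tot = float((Yc ** 2).sum())
    pct = 100.0 * float((pred ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return ShapeResiduals(list(aligned.specimen_ids), resid + mean_shape,
                          slope, pct, sizes, aligned.group_labels)
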