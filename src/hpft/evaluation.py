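"""Precision, robustness and uniformity evaluation of registration results.

Without ground truth for in-vivo footage, registration quality is judged by
self-consistency:

* **Forward-backward (FB) error** — each initial feature is tracked from
  the first frame to the last and back; the distance between its initial
  and returned positions is the FB error, and features returning within
  4 px count as reliable.  PPV (precision percent validation) is the
  reliable count over the initial feature budget.
* **KL divergence** — the spatial distributions of a feature's forward and
  backward trajectories are compared with the (non-symmetric)
  Kullback-Leibler divergence in both directions; a trajectory passes when
  both divergences are below 0.1 and of the same order.
* **Robustness** — the pair is re-registered under M seeded noise
  realizations; for each reference point the sample covariance of its
  registered target positions measures localization stability, scalarized
  as score = 1/(1 + rms scatter); RPV is the fraction of FB-reliable
  features whose score reaches 0.8 (i.e. rms scatter <= 0.25 px).
* **Uniformity** — a per-axis chi-square deviation of the matched
  coordinates from a uniform histogram; lower means more uniform coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .core import HpftConfig, RegistrationResult, hpft_register, propagate_points
from .features import DegenerateGeometryError, detect_features

__all__ = [
    "TrajectoryRecord",
    "RobustnessSample",
    "EvalReport",
    "track_sequence",
    "forward_backward",
    "fb_errors",
    "ppv",
    "kl_divergence",
    "dkl_trajectory_check",
    "dkl_rule",
    "precision_reliability",
    "robustness_ensemble",
    "rpv",
    "uniformity",
]


@dataclass
class TrajectoryRecord:
    feature_id: int
    forward_positions: list[np.ndarray] = field(default_factory=list)
    backward_positions: list[np.ndarray] = field(default_factory=list)
    fb_error: float = np.nan

    @property
    def lost(self) -> bool:
        pos = self.forward_positions or self.backward_positions
        return any(np.any(np.isnan(p)) for p in pos) or not pos


@dataclass
class RobustnessSample:
    feature_id: int
    samples: np.ndarray  # (m, 2) target positions over noise realizations
    cov: np.ndarray  # 2x2
    score: float


@dataclass
class EvalReport:
    ppv: float
    rpv: float
    dkl_pass_count: int
    dkl1: list[float]
    dkl2: list[float]
    uniformity_x: float
    uniformity_y: float
    fb: list[float] = field(default_factory=list)
    initial_count: int = 0
    reliable_count: int = 0
    cov_scores: dict[int, float] = field(default_factory=dict)


def track_sequence(
    frames: list[np.ndarray],
    cfg: HpftConfig | None = None,
    direction: str = "forward",
    initial_points: np.ndarray | None = None,
) -> list[TrajectoryRecord]:
    """Propagate features through consecutive pair registrations.

    ``frames`` are taken in the given order for ``forward`` and reversed
    for ``backward``.  When ``initial_points`` is None, features are
    detected on the first frame of the traversal; a backward pass normally
    receives the forward pass's final positions so FB errors are
    meaningful.  Each point moves per frame pair via its containing
    accepted patch's affine, else via the nearest matched point's
    translation within 30 px, else the trajectory is lost (NaN onward).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    cfg = cfg or HpftConfig()
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    seq = list(frames) if direction == "forward" else list(frames)[::-1]
    if initial_points is None:
        feats = detect_features(seq[0], None, budget=cfg.budget, seed=cfg.seed)
        pts = np.stack([f.xy for f in feats])
    else:
        pts = np.atleast_2d(np.asarray(initial_points, dtype=float))
    n = len(pts)
    records = [TrajectoryRecord(feature_id=i) for i in range(n)]
    attr = "forward_positions" if direction == "forward" else "backward_positions"
    for rec, p in zip(records, pts):
        getattr(rec, attr).append(np.array(p, dtype=float))
    cur = pts.copy()
    for k in range(len(seq) - 1):
        pair_cfg = HpftConfig(**{**cfg.__dict__, "seed": substream(cfg.seed, f"{direction}-pair{k}")})
        try:
            res = hpft_register(seq[k], seq[k + 1], None, pair_cfg)
        except DegenerateGeometryError:
            cur = np.full_like(cur, np.nan)
            for rec in records:
                getattr(rec, attr).append(np.full(2, np.nan))
            continue
        alive = ~np.isnan(cur).any(axis=1)
        nxt = np.full_like(cur, np.nan)
        if alive.any():
            nxt[alive] = propagate_points(res, cur[alive])
        h, w = np.asarray(seq[k + 1]).shape[:2]
        oob = (nxt[:, 0] < 0) | (nxt[:, 0] > w - 1) | (nxt[:, 1] < 0) | (nxt[:, 1] > h - 1)
        nxt[oob] = np.nan
        cur = nxt
        for rec, p in zip(records, cur):
            getattr(rec, attr).append(np.array(p, dtype=float))
    return records


def forward_backward(
    frames: list[np.ndarray],
    cfg: HpftConfig | None = None,
    initial_points: np.ndarray | None = None,
) -> tuple[list[TrajectoryRecord], list[TrajectoryRecord]]:
    """Track forward to the last frame, then backward from where each
    trajectory arrived; records are aligned by feature_id."""
    cfg = cfg or HpftConfig()
    fwd = track_sequence(frames, cfg, "forward", initial_points=initial_points)
    last = np.stack([r.forward_positions[-1] for r in fwd])
    bwd = track_sequence(frames, cfg, "backward", initial_points=last)
    return fwd, bwd


def fb_errors(
    forward: list[TrajectoryRecord], backward: list[TrajectoryRecord]
) -> list[float]:
    """Distance between each feature's initial and backward-returned
    positions; lost trajectories get +inf."""
    out = []
    by_id = {r.feature_id: r for r in backward}
    for f in forward:
        b = by_id.get(f.feature_id)
        if b is None or f.lost or b.lost:
            out.append(float("inf"))
            continue
        start = f.forward_positions[0]
        ret = b.backward_positions[-1]
        err = float(np.hypot(*(start - ret)))
        out.append(err)
        f.fb_error = b.fb_error = err
    return out


def ppv(fb: list[float], initial_count: int, threshold: float = 4.0) -> float:
    """Precision percent validation: count(FB error <= threshold) / budget."""
    if initial_count <= 0:
        raise ValueError("initial_count must be positive")
    if not fb:
        return 0.0
    reliable = sum(1 for e in fb if e <= threshold)
    return reliable / initial_count


def precision_reliability(dkl_pass_count: int, fb_reliable_count: int) -> float:
    """Agreement ratio of the KL check with the FB-error check.

    Near 1 means the two precision estimates agree and the FB-based
    precision can be trusted.
    """
    if fb_reliable_count <= 0:
        raise ValueError("fb_reliable_count must be positive")
    return dkl_pass_count / fb_reliable_count


def kl_divergence(P: np.ndarray, Q: np.ndarray, smoothing: float = 1e-9) -> float:
    """Sum P ln(P/Q) after additive smoothing and renormalization."""
    P = np.asarray(P, dtype=float).ravel()
    Q = np.asarray(Q, dtype=float).ravel()
    if P.shape != Q.shape:
        raise ValueError("histograms must share bin structure")
    P = P + smoothing
    Q = Q + smoothing
    P = P / P.sum()
    Q = Q / Q.sum()
    return float(np.sum(P * np.log(P / Q)))


def _bin_positions(positions: list[np.ndarray], shape: tuple[int, int], bins: int) -> np.ndarray:
    h, w = shape
    pts = np.stack(positions)
    hist, _, _ = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=bins, range=[[0, w], [0, h]]
    )
    return hist


def dkl_trajectory_check(
    forward: TrajectoryRecord,
    backward: TrajectoryRecord,
    frame_shape: tuple[int, int],
    bins: int = 8,
) -> tuple[bool, float, float]:
    """Compare a feature's forward and backward spatial distributions.

    Positions are binned on a ``bins`` x ``bins`` grid over the frame; the
    check passes when both divergences are < 0.1 and within one order of
    magnitude of each other (ratio <= 10, with 0/0 taken as 1).
    """
    if forward.lost or backward.lost:
        return False, float("inf"), float("inf")
    Pf = _bin_positions(forward.forward_positions, frame_shape, bins)
    Pb = _bin_positions(backward.backward_positions, frame_shape, bins)
    Pf = Pf / Pf.sum()
    Pb = Pb / Pb.sum()
    d1 = kl_divergence(Pb, Pf)  # backward || forward
    d2 = kl_divergence(Pf, Pb)
    return dkl_rule(d1, d2), d1, d2


def dkl_rule(d1: float, d2: float, threshold: float = 0.1, order_ratio: float = 10.0) -> bool:
    """Pass iff both divergences are below ``threshold`` and of the same
    order (max/min <= ``order_ratio``; 0/0 counts as ratio 1)."""
    if d1 == 0 and d2 == 0:
        ratio = 1.0
    else:
        lo, hi = sorted([max(d1, 0.0), max(d2, 0.0)])
        ratio = float("inf") if lo == 0 else hi / lo
    return d1 < threshold and d2 < threshold and ratio <= order_ratio


def robustness_ensemble(
    img_ref: np.ndarray,
    img_tgt: np.ndarray,
    cfg: HpftConfig | None = None,
    sigmas: tuple[float, ...] = (2.0, 5.0, 10.0),
    M: int = 30,
    seed: int = 0,
    points: np.ndarray | None = None,
) -> list[RobustnessSample]:
    """Localization scatter of registered points under injected noise.

    The pair is re-registered M times with fresh zero-mean Gaussian noise
    (cycling through ``sigmas``) added to both images.  A point's
    registration site in a realization is its position under the validated
    homographic patch that contains it (points outside every accepted
    patch are unmatched in that realization).  For every fixed
    clean-reference point registered in >= 2 realizations, the sample mean
    and covariance (1/(M-1)) of its target positions are computed;
    score = 1/(1 + rms), rms = sqrt((var_xx + var_yy)/2), so perfect
    stability scores 1 and the 0.8 cutoff corresponds to 0.25 px rms.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    cfg = cfg or HpftConfig()
    img_ref = np.asarray(img_ref)
    img_tgt = np.asarray(img_tgt)
    if points is None:
        feats = detect_features(img_ref, None, budget=cfg.budget, seed=cfg.seed)
        points = np.stack([f.xy for f in feats])
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    collected: list[list[np.ndarray]] = [[] for _ in range(n)]
    for k in range(M):
        sigma = sigmas[k % len(sigmas)]
        rng = np.random.default_rng(substream(seed, f"noise-{k}"))
        nref = np.clip(np.round(img_ref + rng.normal(0, sigma, img_ref.shape)), 0, 255).astype(np.uint8)
        ntgt = np.clip(np.round(img_tgt + rng.normal(0, sigma, img_tgt.shape)), 0, 255).astype(np.uint8)
        pair_cfg = HpftConfig(**{**cfg.__dict__, "seed": substream(seed, f"reg-{k}")})
        try:
            res = hpft_register(nref, ntgt, None, pair_cfg)
        except DegenerateGeometryError:
            continue
        prop = propagate_points(res, points, radius=None)
        for i in range(n):
            if not np.any(np.isnan(prop[i])):
                collected[i].append(prop[i])
    out = []
    for i, samp in enumerate(collected):
        if len(samp) < 2:
            continue
        S = np.stack(samp)
        cov = np.cov(S.T, ddof=1)
        rms = float(np.sqrt((cov[0, 0] + cov[1, 1]) / 2.0))
        out.append(RobustnessSample(feature_id=i, samples=S, cov=cov, score=1.0 / (1.0 + rms)))
    return out


def rpv(
    samples: list[RobustnessSample], reliable_count: int, score_threshold: float = 0.8
) -> float:
    """Robustness percent validation: robust count / FB-reliable count.

    The numerator counts every feature whose registration site stayed
    stable (score >= threshold) across the noise ensemble; the denominator
    is the FB-reliable count. The ratio is capped at 1.
    """
    if reliable_count <= 0:
        raise ValueError("reliable_count must be positive")
    robust = sum(1 for s in samples if s.score >= score_threshold)
    return min(robust / reliable_count, 1.0)


def uniformity(points: np.ndarray, frame_size: tuple[int, int], bins: int = 10) -> tuple[float, float]:
    """Per-axis chi-square deviation from a uniform coordinate histogram.

    Returns (ux, uy) = sum_b (count_b - N/bins)^2 / (N/bins) for the x and
    y coordinates; 0 means perfectly uniform coverage.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 1:
        raise ValueError("need at least one point")
    w, h = frame_size
    N = len(pts)
    expected = N / bins
    out = []
    for axis, extent in ((0, w), (1, h)):
        counts, _ = np.histogram(pts[:, axis], bins=bins, range=(0, extent))
        out.append(float(np.sum((counts - expected) ** 2) / expected))
    return out[0], out[1]


def evaluate_sequence(
    frames: list[np.ndarray],
    cfg: HpftConfig | None = None,
    sigmas: tuple[float, ...] = (2.0, 5.0, 10.0),
    reps: int = 30,
    seed: int = 0,
    bins: int = 8,
    roi_margin: int = 40,
) -> EvalReport:
    """Full evaluation: FB/PPV, per-feature KL checks, robustness/RPV,
    uniformity of the matched coordinates.

    Initial features are restricted to a region of interest ``roi_margin``
    px inside the frame border, so that slow camera drift does not carry
    them out of view over the sequence (features leaving the frame would be
    charged to the tracker even though no registration could recover them).
    """
    cfg = cfg or HpftConfig()
    shape0 = np.asarray(frames[0]).shape[:2]
    roi_mask = np.ones(shape0, dtype=bool)
    m = roi_margin
    if m > 0 and 2 * m < min(shape0):
        roi_mask[m:-m, m:-m] = False  # True = excluded
    else:
        roi_mask[:] = False
    feats0 = detect_features(frames[0], roi_mask, budget=cfg.budget, seed=cfg.seed)
    pts_init = np.stack([f.xy for f in feats0])
    fwd, bwd = forward_backward(frames, cfg, initial_points=pts_init)
    fb = fb_errors(fwd, bwd)
    initial_count = cfg.budget
    p = ppv(fb, initial_count, cfg.fb_threshold)
    reliable = sum(1 for e in fb if e <= cfg.fb_threshold)
    shape = np.asarray(frames[0]).shape[:2]
    d1s, d2s, passes = [], [], 0
    by_id = {r.feature_id: r for r in bwd}
    for f in fwd:
        b = by_id[f.feature_id]
        ok, d1, d2 = dkl_trajectory_check(f, b, shape, bins=bins)
        d1s.append(d1)
        d2s.append(d2)
        passes += int(ok)
    pts0 = np.stack([r.forward_positions[0] for r in fwd])
    samples = robustness_ensemble(
        frames[0], frames[1], cfg, sigmas=sigmas, M=reps, seed=seed, points=pts0
    )
    r = rpv(samples, reliable) if reliable else 0.0
    surviving = np.stack(
        [r_.forward_positions[-1] for r_ in fwd if not r_.lost]
    ) if any(not r_.lost for r_ in fwd) else pts0
    ux, uy = uniformity(surviving, (shape[1], shape[0]))
    return EvalReport(
        ppv=p,
        rpv=r,
        dkl_pass_count=passes,
        dkl1=d1s,
        dkl2=d2s,
        uniformity_x=ux,
        uniformity_y=uy,
        fb=fb,
        initial_count=initial_count,
        reliable_count=reliable,
        cov_scores={s.feature_id: s.score for s in samples},
    )
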