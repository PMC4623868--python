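"""Rule-based excursion detection for sparse nest-centred trajectories.

A fix is classified as part of an *excursion* (a swift, relatively straight
journey away from or between settlement areas) rather than within-range
movement using three heuristics:

1. **Nest buffer (veto).** Fixes within 30 km of the nest are never part of
   an excursion; small-scale movement around the natal site would otherwise
   be misread as travel.
2. **Velocity rule.** Beyond the buffer, a fix with high radial velocity and
   low angular velocity (|v_r| > 5 km/h and |v_theta| < 45 deg/h by default)
   marks directional travel.
3. **Novelty rule.** Beyond the buffer, a fix more than 3 km from *every*
   previous fix of the same bird marks ground not previously visited.

Because the tag transmits at most a handful of fixes per day, a long journey
can contain interior fixes that look locally sedentary; a final pass
relabels runs of at most ``max_gap_fixes`` settlement fixes flanked on both
sides by excursion fixes as part of the same excursion.

Every excursion fix records which rule fired (``velocity``, ``novelty`` or
``gapfill``); settlement fixes carry ``none``. Classification is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import geometry

LABEL_SETTLEMENT = "settlement"
LABEL_EXCURSION = "excursion"

RULE_NONE = "none"
RULE_VELOCITY = "velocity"
RULE_NOVELTY = "novelty"
RULE_GAPFILL = "gapfill"


@dataclass
class ClassifierConfig:
    """Thresholds of the excursion heuristics.

    Parameters
    ----------
    nest_buffer_km : float
        Radius of the nest veto; fixes with r below/equal this are never
        excursion (default 30 km).
    v_r_thresh_kmh : float
        Radial-speed threshold of the velocity rule (default 5 km/h).
    v_theta_thresh_degh : float
        Angular-speed ceiling of the velocity rule (default 45 deg/h).
    novelty_dist_km : float
        A fix farther than this from every earlier fix is novel (default 3 km).
    max_gap_fixes : int
        Longest settlement run bridged by gap relabelling (default 3).
    use_absolute_v_r : bool
        If True (default) the velocity rule tests |v_r|, so the fast inbound
        leg of a round trip also registers; if False, only outbound speed
        (signed v_r) counts.
    """

    nest_buffer_km: float = 30.0
    v_r_thresh_kmh: float = 5.0
    v_theta_thresh_degh: float = 45.0
    novelty_dist_km: float = 3.0
    max_gap_fixes: int = 3
    use_absolute_v_r: bool = True

    def __post_init__(self):
        for name in ("nest_buffer_km", "v_r_thresh_kmh", "v_theta_thresh_degh", "novelty_dist_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if int(self.max_gap_fixes) != self.max_gap_fixes or self.max_gap_fixes < 0:
            raise ValueError("max_gap_fixes must be an integer >= 0")


def velocity_rule(v_r, v_theta, defined, r, cfg: ClassifierConfig):
    """Vectorised velocity heuristic: fast radial, slow angular, outside buffer.

    Undefined velocities (a bird's first fix) never fire.
    """
    v_r = np.asarray(v_r, float)
    v_theta = np.asarray(v_theta, float)
    r = np.asarray(r, float)
    defined = np.asarray(defined, bool)
    speed = np.abs(v_r) if cfg.use_absolute_v_r else v_r
    with np.errstate(invalid="ignore"):
        fired = (
            defined
            & (r > cfg.nest_buffer_km)
            & (speed > cfg.v_r_thresh_kmh)
            & (np.abs(v_theta) < cfg.v_theta_thresh_degh)
        )
    return fired


def novelty_rule_bruteforce(xy, r, cfg: ClassifierConfig):
    """O(n^2) reference implementation of the novelty heuristic.

    Kept deliberately simple; serves as the oracle for the indexed version.
    """
    xy = np.asarray(xy, float)
    r = np.asarray(r, float)
    n = len(xy)
    fired = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if r[i] <= cfg.nest_buffer_km:
            continue
        d2 = np.sum((xy[:i] - xy[i]) ** 2, axis=1)
        fired[i] = d2.min() > cfg.novelty_dist_km**2
    return fired


def novelty_rule(xy, r, cfg: ClassifierConfig):
    """Novelty heuristic via a uniform spatial hash over past fixes.

    For each fix in time order, earlier fixes are binned into square cells
    of side ``novelty_dist_km``; only the 3x3 cell neighbourhood needs to be
    searched for a point within the novelty distance, making the pass O(n)
    for settlement-dominated trajectories. Identical output to
    :func:`novelty_rule_bruteforce`.
    """
    xy = np.asarray(xy, float)
    r = np.asarray(r, float)
    n = len(xy)
    fired = np.zeros(n, dtype=bool)
    cell = float(cfg.novelty_dist_km)
    d2max = cfg.novelty_dist_km**2
    grid: dict[tuple[int, int], list[int]] = {}

    def key(p):
        return (int(np.floor(p[0] / cell)), int(np.floor(p[1] / cell)))

    for i in range(n):
        if i >= 1 and r[i] > cfg.nest_buffer_km:
            kx, ky = key(xy[i])
            novel = True
            for gx in range(kx - 1, kx + 2):
                for gy in range(ky - 1, ky + 2):
                    for j in grid.get((gx, gy), ()):
                        dx = xy[j, 0] - xy[i, 0]
                        dy = xy[j, 1] - xy[i, 1]
                        if dx * dx + dy * dy <= d2max:
                            novel = False
                            break
                    if not novel:
                        break
                if not novel:
                    break
            fired[i] = novel
        grid.setdefault(key(xy[i]), []).append(i)
    return fired


def relabel_gaps(labels, rules, cfg: ClassifierConfig):
    """Bridge short settlement runs flanked by excursion fixes.

    Every maximal run of settlement labels of length <= ``max_gap_fixes``
    that has an excursion fix immediately on *both* sides becomes excursion
    with rule ``gapfill``. Excursion labels never revert. One pass over
    maximal runs reaches the fixed point: relabelling only merges existing
    excursion runs and cannot create a new short flanked run.
    """
    labels = np.asarray(labels).copy()
    rules = np.asarray(rules).copy()
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] == LABEL_SETTLEMENT:
            j = i
            while j < n and labels[j] == LABEL_SETTLEMENT:
                j += 1
            run_len = j - i
            flanked = i > 0 and j < n  # neighbours exist and are excursion by construction
            if flanked and run_len <= cfg.max_gap_fixes:
                labels[i:j] = LABEL_EXCURSION
                rules[i:j] = RULE_GAPFILL
            i = j
        else:
            i += 1
    return labels, rules


def classify(traj, cfg: ClassifierConfig | None = None):
    """Label every fix of a trajectory as settlement or excursion.

    Runs the velocity and novelty rules (velocity checked first for
    provenance), then the gap-relabelling pass. Returns ``(labels, rules)``
    as string arrays aligned with the trajectory's fixes.
    """
    cfg = cfg or ClassifierConfig()
    track = geometry.project(traj)
    polar = geometry.to_polar(track)
    vel = geometry.velocities(polar)

    vel_fired = velocity_rule(vel.v_r, vel.v_theta, vel.defined, polar.r, cfg)
    nov_fired = novelty_rule(track.xy, polar.r, cfg)

    n = len(traj)
    labels = np.full(n, LABEL_SETTLEMENT, dtype=object)
    rules = np.full(n, RULE_NONE, dtype=object)
    labels[vel_fired | nov_fired] = LABEL_EXCURSION
    rules[nov_fired] = RULE_NOVELTY
    rules[vel_fired] = RULE_VELOCITY  # velocity takes provenance precedence
    labels, rules = relabel_gaps(labels, rules, cfg)
    return labels.astype(str), rules.astype(str)


def _round_half_up(value: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def excursion_summary(per_bird) -> pd.DataFrame:
    """Per-bird fix accounting: total fixes, excursion fixes, percentage.

    Parameters
    ----------
    per_bird : mapping of bird_id -> label array, or iterable of
        (bird_id, labels) pairs.

    Returns
    -------
    DataFrame with columns bird_id, n_fixes, n_excursion, pct_excursion
    (percentage rounded half-up to one decimal, as reported in field
    summaries) plus a final "total" row summing the counts.
    """
    if hasattr(per_bird, "items"):
        per_bird = per_bird.items()
    rows = []
    for bird_id, labels in per_bird:
        labels = np.asarray(labels)
        n = len(labels)
        e = int(np.sum(labels == LABEL_EXCURSION))
        pct = _round_half_up(100.0 * e / n) if n else 0.0
        rows.append({"bird_id": str(bird_id), "n_fixes": n, "n_excursion": e, "pct_excursion": pct})
    if not rows:
        return pd.DataFrame(columns=["bird_id", "n_fixes", "n_excursion", "pct_excursion"])
    df = pd.DataFrame(rows).sort_values("pct_excursion", ascending=False, kind="stable")
    total_n = int(df["n_fixes"].sum())
    total_e = int(df["n_excursion"].sum())
    total = {
        "bird_id": "total",
        "n_fixes": total_n,
        "n_excursion": total_e,
        "pct_excursion": _round_half_up(100.0 * total_e / total_n) if total_n else 0.0,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def summary_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute the percentage column of a per-bird count table.

    ``counts`` needs columns bird_id, n_fixes, n_excursion; the rounded
    percentage and a totals row are (re)computed exactly as
    :func:`excursion_summary` does from raw labels.
    """
    df = counts[["bird_id", "n_fixes", "n_excursion"]].copy()
    df["pct_excursion"] = [
        _round_half_up(100.0 * e / n) if n else 0.0
        for n, e in zip(df["n_fixes"], df["n_excursion"])
    ]
    total_n = int(df["n_fixes"].sum())
    total_e = int(df["n_excursion"].sum())
    total = {
        "bird_id": "total",
        "n_fixes": total_n,
        "n_excursion": total_e,
        "pct_excursion": _round_half_up(100.0 * total_e / total_n) if total_n else 0.0,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
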