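"""Iterative contact-based discovery of the main unbinding CV.

The protocol mirrors automated ligand-unbinding path discovery: an
unbiased exploration identifies the initial ligand-protein contacts
(distances persistently below d_in = 3.5 Å); their sum becomes the main
collective variable, which is pulled by a harmonic restraint whose
target grows by d_tar = 1 Å per active distance each iteration
(D = D0 + M d_tar, reached progressively through the iteration, force
constant k = 20).  After each iteration, newly persistent contacts are
added and contacts whose recent mean exceeds d_out = 6 Å - or whose
recent variance exceeds d_var - are dropped.  The protocol terminates
when no active contact remains: the ligand has left the pocket.

Contacts are tracked per anchor site of a toy 2D pocket system (or any
user-supplied per-frame distance table); equivalence groups of anchors
can be merged to a centre-of-mass pseudo-site first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import LangevinParams, simulate
from .potentials import BiasTerm, Potential, SumDistanceCV

__all__ = [
    "ProtocolParams",
    "ContactRecord",
    "ContactSet",
    "EquivalenceGroup",
    "AnchoredParticleSystem",
    "UnbindingResult",
    "detect_initial_contacts",
    "bias_target",
    "update_contacts",
    "run_unbinding",
    "merge_equivalent",
]


@dataclass
class ProtocolParams:
    """Cutoffs and schedule constants of the unbinding protocol.

    d_in                 : inclusion cutoff, Å (contact when below)
    d_out                : removal cutoff on the windowed mean, Å
    d_var                : removal cutoff on the windowed spread; interpreted
                           as a variance threshold in Å² by default
                           (var_mode="variance") or as a standard deviation
                           in Å (var_mode="std")
    d_tar                : per-distance target increment per iteration, Å
    force_constant       : harmonic bias stiffness, energy units per Å²
    persistence_fraction : fraction of frames below d_in required to add a
                           contact (strictly greater than)
    iteration_length     : frames simulated per iteration
    evaluation_window    : trailing frames used for the add/remove rules
    removal_mode         : "mean" (windowed mean beyond d_out) or
                           "any_frame" (any windowed frame beyond d_out)
    """

    d_in: float = 3.5
    d_out: float = 6.0
    d_var: float = 1.0
    var_mode: str = "variance"
    d_tar: float = 1.0
    force_constant: float = 20.0
    persistence_fraction: float = 0.5
    iteration_length: int = 10_000
    evaluation_window: int = 5_000
    removal_mode: str = "mean"
    max_iterations: int = 50

    def __post_init__(self):
        if not 0 < self.d_in < self.d_out:
            raise ValueError("need 0 < d_in < d_out")
        if self.d_tar < 0:
            raise ValueError("d_tar must be >= 0")
        if not 0 < self.persistence_fraction <= 1:
            raise ValueError("persistence_fraction must be in (0, 1]")
        if self.var_mode not in ("variance", "std"):
            raise ValueError("var_mode must be 'variance' or 'std'")
        if self.removal_mode not in ("mean", "any_frame"):
            raise ValueError("removal_mode must be 'mean' or 'any_frame'")


@dataclass
class ContactRecord:
    """Lifecycle of one tracked ligand-anchor distance."""

    id: str
    status: str = "candidate"  # candidate -> active -> removed
    added_iteration: int | None = None
    removed_iteration: int | None = None
    removal_reason: str | None = None
    removal_stats: dict | None = None

    _TRANSITIONS = {"candidate": {"active"}, "active": {"removed"}, "removed": set()}

    def transition(self, new_status: str) -> None:
        if new_status not in self._TRANSITIONS[self.status]:
            raise ValueError(f"illegal transition {self.status} -> {new_status}")
        self.status = new_status


class ContactSet:
    """The evolving set of contact records, with per-iteration history."""

    def __init__(self, ids):
        self.records = {i: ContactRecord(id=i) for i in ids}
        self.history: list[dict] = []

    @property
    def active_ids(self) -> list:
        return [i for i, r in self.records.items() if r.status == "active"]

    @property
    def candidate_ids(self) -> list:
        return [i for i, r in self.records.items() if r.status == "candidate"]

    def activate(self, contact_id, iteration: int) -> None:
        rec = self.records[contact_id]
        rec.transition("active")
        rec.added_iteration = iteration

    def remove(self, contact_id, iteration: int, reason: str, stats: dict) -> None:
        rec = self.records[contact_id]
        rec.transition("removed")
        rec.removed_iteration = iteration
        rec.removal_reason = reason
        rec.removal_stats = stats

    def log(self, iteration: int, **info) -> None:
        self.history.append({"iteration": iteration,
                             "active": list(self.active_ids), **info})

    def audit_removals(self, params: ProtocolParams) -> bool:
        """Every removed contact violated the mean or variance rule."""
        for rec in self.records.values():
            if rec.status != "removed":
                continue
            st = rec.removal_stats or {}
            spread_limit = (params.d_var if params.var_mode == "variance"
                            else params.d_var**2)
            if not (st.get("mean", -np.inf) > params.d_out
                    or st.get("variance", -np.inf) > spread_limit):
                return False
        return True


def _as_table(distances):
    """Accept a DataFrame or array; return (values, ids)."""
    if isinstance(distances, pd.DataFrame):
        return distances.to_numpy(dtype=float), list(distances.columns)
    arr = np.atleast_2d(np.asarray(distances, dtype=float))
    return arr, [f"pair{i}" for i in range(arr.shape[1])]


def detect_initial_contacts(distances, params: ProtocolParams) -> ContactSet:
    """Initial ContactSet from an unbiased exploration distance table.

    A pair becomes an active contact when its distance is below d_in for
    strictly more than ``persistence_fraction`` of the frames.
    """
    values, ids = _as_table(distances)
    if values.shape[0] == 0:
        raise ValueError("empty distance table")
    contacts = ContactSet(ids)
    below = (values < params.d_in).mean(axis=0)
    for j, cid in enumerate(ids):
        if below[j] > params.persistence_fraction:
            contacts.activate(cid, iteration=0)
    return contacts


def bias_target(D0: float, M: int, params: ProtocolParams) -> float:
    """Next iteration's CV target: D = D0 + M * d_tar."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return D0 + M * params.d_tar


def update_contacts(
    window, contacts: ContactSet, params: ProtocolParams, iteration: int
) -> ContactSet:
    """Apply the add/remove rules on the trailing evaluation window.

    ``window`` is a distance table (evaluation_window frames x all
    tracked pairs, same column order/ids as the contact set).  Candidates
    persistently below d_in are activated; actives whose windowed mean
    exceeds d_out (or any frame, in "any_frame" mode) or whose windowed
    variance exceeds d_var are removed.  Mutates and returns the set.
    """
    values, ids = _as_table(window)
    if list(contacts.records) != ids:
        raise ValueError("window columns do not match tracked contacts")
    mean = values.mean(axis=0)
    var = values.var(axis=0)
    frac_below = (values < params.d_in).mean(axis=0)
    spread = var if params.var_mode == "variance" else np.sqrt(var)

    for j, cid in enumerate(ids):
        rec = contacts.records[cid]
        if rec.status == "candidate" and frac_below[j] > params.persistence_fraction:
            contacts.activate(cid, iteration)
        elif rec.status == "active":
            beyond = (values[:, j].max() > params.d_out
                      if params.removal_mode == "any_frame"
                      else mean[j] > params.d_out)
            stats = {"mean": float(mean[j]), "variance": float(var[j])}
            if beyond:
                contacts.remove(cid, iteration, "distance", stats)
            elif spread[j] > params.d_var:
                contacts.remove(cid, iteration, "variance", stats)
    return contacts


# ---------------------------------------------------------------------------
# toy dynamics backend
# ---------------------------------------------------------------------------


class AnchoredParticleSystem:
    """One mobile particle in a 2D pocket with fixed, labelled anchor sites.

    The dynamics backend for the toy unbinding protocol: exposes
    restrained Langevin sampling and per-frame particle-anchor distances.
    """

    def __init__(self, potential: Potential, anchors: dict,
                 langevin: LangevinParams | None = None):
        self.potential = potential
        self.anchors = {k: np.asarray(v, dtype=float) for k, v in anchors.items()}
        self.langevin = langevin or LangevinParams(step_size=0.005, n_steps=10_000)

    @property
    def anchor_ids(self) -> list:
        return list(self.anchors)

    def distance_table(self, frames: np.ndarray) -> pd.DataFrame:
        """Frames (n_frames, 2) -> distances to every anchor (Å)."""
        frames = np.atleast_2d(np.asarray(frames, dtype=float))
        cols = {
            cid: np.linalg.norm(frames - pos, axis=1)
            for cid, pos in self.anchors.items()
        }
        return pd.DataFrame(cols)

    def cv_for(self, ids) -> SumDistanceCV:
        return SumDistanceCV([self.anchors[i] for i in ids])

    def run(self, x0, n_steps: int, seed: int, bias: BiasTerm | None = None):
        params = LangevinParams(
            step_size=self.langevin.step_size,
            friction=self.langevin.friction,
            kT=self.langevin.kT,
            n_steps=n_steps,
            stride=self.langevin.stride,
            seed=seed,
        )
        traj = simulate(self.potential, params, bias=bias, x0=np.asarray(x0))
        return traj.frames[0]


@dataclass
class UnbindingResult:
    """Everything an unbinding run produces, for auditing and string seeding."""

    frames: np.ndarray  # concatenated trajectory (n_frames, 2)
    contacts: ContactSet
    cv_series: np.ndarray  # sum of *all* tracked distances per frame
    iteration_log: list
    terminated: bool

    def final_distances(self, system: AnchoredParticleSystem) -> pd.Series:
        return system.distance_table(self.frames[-1:]).iloc[-1]


def run_unbinding(
    system: AnchoredParticleSystem,
    params: ProtocolParams,
    seed: int = 0,
    x0=None,
    contacts: ContactSet | None = None,
) -> UnbindingResult:
    """Run the full iterative unbinding protocol on a toy pocket system.

    Starts with an unbiased exploration (used for contact detection when
    no initial ContactSet is given), then iterates biased pulls with the
    per-iteration re-targeted sum-of-active-distances CV until the active
    set empties or ``max_iterations`` is hit.
    """
    seeds = np.random.SeedSequence(seed).generate_state(params.max_iterations + 1)
    seeds = seeds % (2**31)
    x = np.asarray(x0 if x0 is not None else np.zeros(2), dtype=float)

    frames = system.run(x, params.iteration_length, int(seeds[0]))
    if contacts is None:
        contacts = detect_initial_contacts(system.distance_table(frames), params)
    all_frames = [frames]
    log = []
    x = frames[-1]

    terminated = not contacts.active_ids
    for it in range(1, params.max_iterations + 1):
        active = contacts.active_ids
        if not active:
            terminated = True
            break
        cv = system.cv_for(active)
        D0 = float(cv.value(x))
        D = bias_target(D0, M=len(active), params=params)
        bias = BiasTerm(cv=cv, center=D, force_constant=params.force_constant,
                        schedule="linear", start_center=D0)
        frames = system.run(x, params.iteration_length, int(seeds[it]), bias=bias)
        x = frames[-1]
        all_frames.append(frames)

        window = system.distance_table(frames[-params.evaluation_window:])
        update_contacts(window, contacts, params, iteration=it)
        contacts.log(it, D0=D0, D=D, M=len(active))
        log.append({"iteration": it, "D0": D0, "D": D, "M": len(active),
                    "active_after": list(contacts.active_ids)})
    else:
        terminated = not contacts.active_ids

    frames = np.concatenate(all_frames, axis=0)
    cv_all = system.distance_table(frames).to_numpy().sum(axis=1)
    return UnbindingResult(frames=frames, contacts=contacts, cv_series=cv_all,
                           iteration_log=log, terminated=terminated)


# ---------------------------------------------------------------------------
# equivalence groups
# ---------------------------------------------------------------------------


@dataclass
class EquivalenceGroup:
    """Anchors interconvertible by an internal rotation, merged to one site."""

    member_ids: tuple

    def __post_init__(self):
        self.member_ids = tuple(self.member_ids)


def merge_equivalent(groups, anchors: dict) -> dict:
    """Replace each group's members by their centre-of-mass pseudo-site.

    ``anchors`` maps id -> position; returns a new mapping where every
    group is collapsed to ``"+".join(member_ids)`` at the unweighted mean
    position.  Groups must be disjoint.
    """
    seen = set()
    for g in groups:
        overlap = seen & set(g.member_ids)
        if overlap:
            raise ValueError(f"overlapping equivalence groups: {sorted(overlap)}")
        seen |= set(g.member_ids)
        missing = set(g.member_ids) - set(anchors)
        if missing:
            raise ValueError(f"unknown anchor ids: {sorted(missing)}")

    merged = {k: np.asarray(v, dtype=float) for k, v in anchors.items()
              if k not in seen}
    for g in groups:
        pos = np.mean([np.asarray(anchors[i], dtype=float)
                       for i in g.member_ids], axis=0)
        merged["+".join(g.member_ids)] = pos
    return merged
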