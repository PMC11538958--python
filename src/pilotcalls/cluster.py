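"""Density clustering of 2-D call projections, the auditable manual
review loop, and the final call-type catalogue.

HDBSCAN proposes clusters (label -1 = noise / unclustered); a plain-text
review script captures the manual merge/split/exclude/relabel decisions
so that the "manual validation" step is reproducible and diffable; the
final repertoire keeps only types occurring at least three times, with
rarer clusters returned to the unclassified pool.  Noise points are
reported but never auto-assigned to a type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.metrics import adjusted_rand_score

#: a call type must occur at least this often to enter the repertoire
MIN_OCCURRENCE = 3
#: jittered call types trace out extended manifolds in the 2-D
#: projection; smaller values oversplit them into micro-clusters
DEFAULT_MIN_CLUSTER_SIZE = 10


@dataclass
class CallType:
    """One cluster-validated category of the repertoire."""

    type_label: str
    call_ids: list
    per_dataset: dict

    @property
    def occurrence(self) -> int:
        return len(self.call_ids)

    @property
    def exemplar(self) -> str:
        return self.call_ids[0]


@dataclass
class Repertoire:
    """The catalogue: call types plus classification bookkeeping."""

    types: list
    n_detected: int
    n_classified: int

    @property
    def n_unclassified(self) -> int:
        return self.n_detected - self.n_classified

    def occurrence_matrix(self) -> pd.DataFrame:
        """Types x datasets occurrence counts."""
        rows = {t.type_label: dict(t.per_dataset) for t in self.types}
        return pd.DataFrame(rows).T.fillna(0).astype(int).sort_index()


def run_hdbscan(points, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE) -> dict:
    """Cluster 2-D projections; returns ``{call_id: label}`` with -1 = noise.

    ``points`` is a mapping ``call_id -> (x, y)`` or a DataFrame with
    columns ``call_id, x, y``.  Labels are dense-coded from 0 and the
    result is deterministic for a fixed input order.
    """
    if isinstance(points, pd.DataFrame):
        ids = points["call_id"].tolist()
        xy = points[["x", "y"]].to_numpy(dtype=float)
    else:
        ids = list(points)
        xy = np.asarray([points[i] for i in ids], dtype=float)
    if len(ids) < min_cluster_size:
        raise ValueError(f"need at least min_cluster_size={min_cluster_size} points, got {len(ids)}")
    if np.allclose(xy, xy[0]):
        return dict.fromkeys(ids, 0)  # degenerate: all points coincide
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(xy)
    return dict(zip(ids, (int(l) for l in labels)))


def parse_review_script(text: str):
    """Parse the line-oriented review script into a list of operations.

    Verbs (one per line, ``#`` comments and blank lines ignored):

    * ``merge A B`` — move every call of cluster B into cluster A;
    * ``split NEW id1 id2 ...`` — move the listed calls to cluster NEW;
    * ``exclude id1 id2 ...`` — mark the listed calls as noise (-1);
    * ``relabel A NAME`` — rename cluster A to the text NAME (e.g. 28b).
    """
    ops = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        verb = parts[0].lower()
        if verb == "merge" and len(parts) == 3:
            ops.append((lineno, "merge", parts[1], parts[2]))
        elif verb == "split" and len(parts) >= 3:
            ops.append((lineno, "split", parts[1], parts[2:]))
        elif verb == "exclude" and len(parts) >= 2:
            ops.append((lineno, "exclude", parts[1:]))
        elif verb == "relabel" and len(parts) == 3:
            ops.append((lineno, "relabel", parts[1], parts[2]))
        else:
            raise ValueError(f"review script line {lineno}: cannot parse {raw!r}")
    return ops


def _norm(label):
    """Labels compare as strings so `merge 2 3` matches integer labels."""
    return str(label)


def apply_review(assignments: dict, script: str):
    """Apply a review script to ``{call_id: label}`` assignments.

    Operations are applied in file order; unknown labels or call ids
    raise ``ValueError`` citing the script line.  Returns
    ``(revised_assignments, audit_log)`` where the audit log records one
    human-readable line per applied operation.  The total call count is
    never changed.
    """
    out = dict(assignments)
    log = []
    for op in parse_review_script(script):
        lineno = op[0]
        if op[1] == "merge":
            _, _, a, b = op
            labels = {_norm(v) for v in out.values()}
            for lbl in (a, b):
                if lbl not in labels:
                    raise ValueError(f"review script line {lineno}: unknown cluster label {lbl!r}")
            moved = [cid for cid, v in out.items() if _norm(v) == b]
            for cid in moved:
                out[cid] = next(v for v in out.values() if _norm(v) == a)
            log.append(f"line {lineno}: merge {b} -> {a} ({len(moved)} calls)")
        elif op[1] == "split":
            _, _, new, ids = op
            for cid in ids:
                if cid not in out:
                    raise ValueError(f"review script line {lineno}: unknown call_id {cid!r}")
            for cid in ids:
                out[cid] = new
            log.append(f"line {lineno}: split {len(ids)} calls -> {new}")
        elif op[1] == "exclude":
            _, _, ids = op
            for cid in ids:
                if cid not in out:
                    raise ValueError(f"review script line {lineno}: unknown call_id {cid!r}")
            for cid in ids:
                out[cid] = -1
            log.append(f"line {lineno}: exclude {len(ids)} calls")
        else:  # relabel
            _, _, a, name = op
            if a not in {_norm(v) for v in out.values()}:
                raise ValueError(f"review script line {lineno}: unknown cluster label {a!r}")
            for cid, v in out.items():
                if _norm(v) == a:
                    out[cid] = name
            log.append(f"line {lineno}: relabel {a} -> {name}")
    return out, log


def finalize_repertoire(assignments: dict, datasets: dict | None = None,
                        min_occurrence: int = MIN_OCCURRENCE) -> Repertoire:
    """Build the final catalogue from ``{call_id: label}`` assignments.

    Clusters with fewer than ``min_occurrence`` members are dropped as
    "rare" and their calls returned to the unclassified pool, together
    with noise points (-1).  ``datasets`` maps ``call_id -> dataset`` for
    the per-dataset occurrence matrix (one pseudo-dataset otherwise).
    """
    datasets = datasets or {}
    groups: dict = {}
    for cid, lbl in assignments.items():
        if _norm(lbl) == "-1":
            continue
        groups.setdefault(_norm(lbl), []).append(cid)
    types = []
    n_classified = 0
    for lbl in sorted(groups):
        ids = sorted(groups[lbl])
        if len(ids) < min_occurrence:
            continue
        per_ds: dict = {}
        for cid in ids:
            ds = datasets.get(cid, "all")
            per_ds[ds] = per_ds.get(ds, 0) + 1
        types.append(CallType(lbl, ids, per_ds))
        n_classified += len(ids)
    return Repertoire(types, n_detected=len(assignments), n_classified=n_classified)


def recovery_score(assignments: dict, truth: dict):
    """Chance-adjusted agreement between predicted clusters and planted types.

    Noise points (label -1) are excluded from the agreement index and
    reported separately.  Returns ``(ari, contingency, n_noise)`` where
    ``ari`` is the adjusted Rand index over non-noise calls and
    ``contingency`` a types x clusters count table.
    """
    shared = sorted(set(assignments) & set(truth))
    if not shared:
        raise ValueError("assignments and ground truth share no call ids")
    pred = [assignments[c] for c in shared]
    true = [truth[c] for c in shared]
    keep = [i for i, p in enumerate(pred) if _norm(p) != "-1"]
    n_noise = len(shared) - len(keep)
    if not keep:
        return 0.0, pd.DataFrame(), n_noise
    ari = float(adjusted_rand_score([true[i] for i in keep], [_norm(pred[i]) for i in keep]))
    contingency = pd.crosstab(
        pd.Series([true[i] for i in keep], name="true_type"),
        pd.Series([_norm(pred[i]) for i in keep], name="cluster"))
    return ari, contingency, n_noise
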