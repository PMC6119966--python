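"""Simulated site/aggregator topology with explicit message accounting.

Every decentralized protocol in this package is executed as plain function
calls on per-site data containers, but each payload that *would* cross the
network is recorded in a :class:`MessageLog`.  Payload sizes are counted in
real scalars (matrix entries), not bytes, because the communication costs of
the protocols are naturally expressed in matrix dimensions.  Closed-form
predictions for those costs live here too, so a completed run can be audited
against the formula it is supposed to obey.

The aggregator is modeled as one distinguished site: it is a peer that also
merges messages, not a privileged master, and it may hold data of its own.
All rounds are synchronous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "SiteDataset",
    "Message",
    "MessageLog",
    "BandwidthModel",
    "CollinearityError",
    "UnderDeterminedSiteError",
    "EmptyLogError",
    "partition_dataset",
    "predicted_dgica_bandwidth",
    "predicted_dkmeans_bandwidth",
    "audit_log",
    "load_topology",
    "AGGREGATOR",
]

#: Conventional label for the aggregator site in logs and topology files.
AGGREGATOR = "AGG"


class CollinearityError(np.linalg.LinAlgError):
    """A (local or aggregated) design matrix is rank deficient."""


class UnderDeterminedSiteError(ValueError):
    """A site ended up with fewer rows than free parameters allow."""


class EmptyLogError(ValueError):
    """An audit was requested on a log that recorded no messages."""


@dataclass
class SiteDataset:
    """One site's private slice of a regression problem.

    The design matrix is augmented: its last column is the constant-1
    intercept column.  The response may be a single column ``(n_j,)`` or a
    stack of ``V`` targets ``(n_j, V)`` — e.g. one column per brain voxel —
    sharing the same design.  Raw rows never leave the site; only summary
    statistics (weights, Gram matrices, gradients, error sums) are ever
    placed on the wire.
    """

    site_id: str
    design: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be 2-D (n_j x (d+1))")
        if self.design.shape[0] < 1:
            raise ValueError("a site must hold at least one sample")
        if self.response.shape[0] != self.design.shape[0]:
            raise ValueError(
                f"site {self.site_id!r}: design has {self.design.shape[0]} rows "
                f"but response has {self.response.shape[0]}"
            )
        if not np.allclose(self.design[:, -1], 1.0):
            raise ValueError(
                f"site {self.site_id!r}: last design column must be the "
                "constant-1 intercept column"
            )

    @property
    def n_j(self) -> int:
        """Number of local samples (the site's weight in aggregations)."""
        return self.design.shape[0]

    @property
    def n_params(self) -> int:
        """Number of regression parameters d+1 (intercept included)."""
        return self.design.shape[1]

    @property
    def response_2d(self) -> np.ndarray:
        """Response as an (n_j, V) matrix regardless of input shape."""
        return self.response.reshape(self.n_j, -1)


@dataclass(frozen=True)
class Message:
    round: int
    sender: str
    receiver: str
    scalar_count: int


class MessageLog:
    """Ordered record of every simulated transmission.

    ``scalar_count`` is the exact number of real scalars in the payload.
    Rounds must be non-decreasing, mirroring the synchronous protocols.
    """

    def __init__(self) -> None:
        self.records: list[Message] = []

    def send(self, round: int, sender: str, receiver: str, scalar_count: int) -> None:
        if round < 0:
            raise ValueError("round must be >= 0")
        if scalar_count < 0:
            raise ValueError("scalar_count must be >= 0")
        if self.records and round < self.records[-1].round:
            raise ValueError("rounds must be non-decreasing")
        self.records.append(Message(round, sender, receiver, int(scalar_count)))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def next_round(self) -> int:
        return self.records[-1].round + 1 if self.records else 0

    def total(
        self,
        site: str | None = None,
        direction: str = "both",
        sender: str | None = None,
        rounds: Iterable[int] | None = None,
    ) -> int:
        """Sum scalar counts, optionally filtered.

        direction: "sent" counts messages the site emitted, "received"
        messages addressed to it, "both" their sum.  ``sender`` further
        restricts received messages to a particular origin (useful for
        counting only aggregator broadcasts at a leaf site).
        """
        if direction not in ("sent", "received", "both"):
            raise ValueError("direction must be 'sent', 'received' or 'both'")
        round_set = set(rounds) if rounds is not None else None
        tot = 0
        for m in self.records:
            if round_set is not None and m.round not in round_set:
                continue
            if site is None:
                tot += m.scalar_count
                continue
            if direction in ("sent", "both") and m.sender == site:
                tot += m.scalar_count
            if direction in ("received", "both") and m.receiver == site:
                if sender is None or m.sender == sender:
                    tot += m.scalar_count
        return tot

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            [(m.round, m.sender, m.receiver, m.scalar_count) for m in self.records],
            columns=["round", "sender", "receiver", "scalar_count"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MessageLog":
        import pandas as pd

        log = cls()
        for row in pd.read_csv(path).itertuples(index=False):
            log.send(int(row.round), str(row.sender), str(row.receiver), int(row.scalar_count))
        return log


@dataclass
class BandwidthModel:
    """Dimensions entering the closed-form communication formulas.

    d     feature/voxel dimension
    r     component count (spatial components / connectivity rank)
    s     number of sites in the consortium (aggregator included)
    k     number of clusters
    J     number of synchronized iterations
    w     sliding-window length
    M_i   per-site instance counts (windows entering clustering)
    E_i   per-site exemplar counts
    """

    d: int = 1
    r: int = 1
    s: int = 1
    k: int = 1
    J: int = 1
    w: int = 1
    M_i: Sequence[int] = field(default_factory=tuple)
    E_i: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("d", "r", "s", "k", "w"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.J < 0:
            raise ValueError("J must be >= 0")


def predicted_dgica_bandwidth(model: BandwidthModel, is_aggregator: bool = False) -> int:
    """Scalars moved by one site during decentralized group ICA.

    A non-aggregator site forwards one d x r eigenvector package along the
    peer chain and receives the r x r unmixing matrix: d*r + r**2.  The
    aggregator receives the final d x r package and accounts one r x r
    broadcast per consortium site: d*r + r**2 * s.
    """
    if is_aggregator:
        return model.d * model.r + model.r**2 * model.s
    return model.d * model.r + model.r**2


def predicted_dkmeans_bandwidth(
    model: BandwidthModel,
    is_aggregator: bool = False,
    feature_size: int | None = None,
) -> int:
    """Scalars uploaded over J decentralized K-Means iterations.

    Each iteration a site uploads its k local centroids.  With full r x r
    connectivity matrices each centroid costs r**2 scalars; when centroids
    are stored as the strict upper triangle the caller passes
    ``feature_size=r*(r-1)//2``.  The aggregator rebroadcasts merged
    centroids to all s sites, multiplying the total by s.
    """
    f = model.r**2 if feature_size is None else int(feature_size)
    per_iter = f * model.k
    total = per_iter * model.J
    return total * model.s if is_aggregator else total


def audit_log(
    log: MessageLog,
    predicted: int,
    role_filter: str,
    direction: str = "sent",
    sender: str | None = None,
    rounds: Iterable[int] | None = None,
) -> bool:
    """Check a completed run's logged traffic against a closed-form count.

    The default convention counts scalars the filtered site *sent*; pass
    ``direction="received"`` (optionally with ``sender=AGGREGATOR``) to count
    broadcasts it consumed, or ``direction="both"`` for the sum.  Raises
    :class:`EmptyLogError` when no protocol has run.
    """
    if len(log) == 0:
        raise EmptyLogError("cannot audit an empty message log")
    return log.total(site=role_filter, direction=direction, sender=sender, rounds=rounds) == predicted


def partition_dataset(
    pooled: SiteDataset,
    proportions: Sequence[float],
    seed: int,
) -> list[SiteDataset]:
    """Split a pooled dataset row-wise into simulated sites.

    Rows are permuted with a seeded generator and dealt out in blocks whose
    sizes follow ``proportions`` (largest-remainder rounding, so the split is
    exhaustive).  Concatenating the outputs recovers the pooled rows up to
    that permutation.  Each site must receive at least d+2 rows so its local
    least-squares problem is over-determined.
    """
    props = np.asarray(proportions, dtype=float)
    if props.ndim != 1 or len(props) < 1:
        raise ValueError("proportions must be a non-empty 1-D sequence")
    if np.any(props <= 0):
        raise ValueError("proportions must be positive")
    if not np.isclose(props.sum(), 1.0, atol=1e-8):
        raise ValueError(f"proportions must sum to 1, got {props.sum()}")

    n = pooled.n_j
    raw = props * n
    sizes = np.floor(raw).astype(int)
    # largest remainder: hand out the leftover rows
    for idx in np.argsort(-(raw - sizes))[: n - sizes.sum()]:
        sizes[idx] += 1
    min_rows = pooled.n_params + 1  # d+2 with the intercept counted in n_params
    if np.any(sizes < min_rows):
        raise UnderDeterminedSiteError(
            f"partition produces a site with fewer than {min_rows} rows: {sizes.tolist()}"
        )

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    y2 = pooled.response_2d
    out: list[SiteDataset] = []
    start = 0
    for j, size in enumerate(sizes):
        rows = perm[start : start + size]
        start += size
        resp = y2[rows]
        if pooled.response.ndim == 1:
            resp = resp.ravel()
        out.append(SiteDataset(f"site{j}", pooled.design[rows], resp))
    return out


def load_topology(path) -> dict:
    """Read a YAML topology: site labels, aggregator role, chain order.

    Expected keys: ``sites`` (ordered list of labels) and ``aggregator``
    (one of those labels; defaults to the last site, the terminal node of
    the peer-to-peer reduction chain).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    sites = list(cfg["sites"])
    if len(sites) != len(set(sites)):
        raise ValueError("duplicate site labels in topology")
    agg = cfg.get("aggregator", sites[-1])
    if agg not in sites:
        raise ValueError(f"aggregator {agg!r} is not one of the sites")
    return {"sites": sites, "aggregator": agg}
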