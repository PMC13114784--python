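"""Synthetic domain-architecture generator with ground truth.

Emulates the statistical structure the analysis assumes: a family
universe with role propensities (host-only / insert-only / versatile /
never-insert), log-normal domain sizes with inserts systematically
smaller than hosts, an insertion grammar producing linear,
single-insertion, multi-insertion-per-gap and nested architectures with
every gap >= the detection threshold by construction, and toy Cα traces
whose N/C-termini distance is drawn from role-appropriate distributions.
The grammar guarantees well-formedness (no straddling inserts, no
overlaps), so any disagreement between detection output and ground truth
is a detector bug; deliberately tricky inputs (boundary gaps, equal-gap
ties, side-by-side and discontinuous inserts) come from the separate
adversarial fixture builder.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError
from .io import CaTrace
from .model import DomainInstance, FamilyKey, ProteinArchitecture, ResidueRange

__all__ = [
    "SyntheticConfig",
    "SyntheticFamily",
    "SyntheticGroundTruth",
    "sample_family_universe",
    "generate_architectures",
    "generate_toy_traces",
    "generate_adversarial",
    "make_nested_protein",
]

ARCHITECTURE_LABELS = ["a.2", "a.6", "a.7", "a.9", "a.12", "a.17", "a.19"]

HOST_CAPABLE = ("host_only", "versatile")
INSERT_CAPABLE = ("insert_only", "versatile")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror the study conditions.

    Size means follow the observed family-level means (hosts ~241, inserts
    ~133 residues); termini medians follow the observed insert/background
    medians (14.3 / 29.8 Å); the multidomain fraction and per-protein
    insertion probability echo the dataset-level rates (~48% multidomain,
    ~20% of multidomain proteins with an insertion).
    """

    n_proteins: int = 500
    n_families: int = 60
    role_propensity: dict = field(
        default_factory=lambda: {
            "host_only": 0.12,
            "insert_only": 0.12,
            "versatile": 0.50,
            "never_insert": 0.26,
        }
    )
    p_tgroup_only: float = 0.05
    p_multidomain: float = 0.476
    p_insertion: float = 0.20
    p_nest: float = 0.15
    p_multi_insert: float = 0.05
    max_depth: int = 6
    multidomain_extra_mean: float = 1.5  # Poisson mean for domains beyond 2
    host_length_mean: float = 241.2
    host_length_sd: float = 100.0
    insert_length_mean: float = 133.4
    insert_length_sd: float = 55.0
    min_insert_length: int = 30
    min_host_length: int = 40
    linker: int = 2
    min_gap: int = 30
    insert_termini_median: float = 14.3
    insert_termini_sigma: float = 0.25
    background_termini_median: float = 29.8
    background_termini_sigma: float = 0.30
    ca_spacing: float = 3.8
    seed: int = 17

    def validate(self) -> None:
        probs = self.role_propensity
        if set(probs) != {"host_only", "insert_only", "versatile", "never_insert"}:
            raise ConfigError("role_propensity must cover the four roles")
        if any(p < 0 for p in probs.values()) or not math.isclose(
            sum(probs.values()), 1.0, abs_tol=1e-9
        ):
            raise ConfigError("role propensities must be >= 0 and sum to 1")
        for name in ("p_tgroup_only", "p_multidomain", "p_insertion", "p_nest", "p_multi_insert"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")
        for name in (
            "host_length_mean", "host_length_sd", "insert_length_mean",
            "insert_length_sd", "insert_termini_median", "insert_termini_sigma",
            "background_termini_median", "background_termini_sigma", "ca_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_insert_length + 2 * self.linker < self.min_gap:
            raise ConfigError(
                "infeasible: min_insert_length + 2*linker < min_gap — generated "
                "gaps could fall below the detection threshold"
            )


@dataclass(frozen=True)
class SyntheticFamily:
    f_id: str
    role: str
    architecture_label: str
    host_log_mu: float  # log-space location of host-role lengths
    insert_log_mu: float  # log-space location of insert-role lengths
    log_sigma: float

    @property
    def key(self) -> FamilyKey:
        return FamilyKey(self.f_id)


@dataclass
class SyntheticGroundTruth:
    """The generator's true events, roles and summary statistics."""

    events: list[tuple[str, str, str, int]]  # (protein_id, host_uid, insert_uid, depth)
    family_roles: dict[str, str]
    n_proteins: int = 0
    n_multidomain: int = 0
    n_proteins_with_insertion: int = 0
    prevalence: float = 0.0
    depth_histogram: dict[int, int] = field(default_factory=dict)
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def event_keys(self) -> set[tuple[str, str, str]]:
        return {(p, h, i) for p, h, i, _ in self.events}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "events": [list(e) for e in self.events],
                    "family_roles": self.family_roles,
                    "n_proteins": self.n_proteins,
                    "n_multidomain": self.n_multidomain,
                    "n_proteins_with_insertion": self.n_proteins_with_insertion,
                    "prevalence": self.prevalence,
                    "depth_histogram": {str(k): v for k, v in self.depth_histogram.items()},
                    "seed": self.seed,
                    "config": self.config,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "SyntheticGroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            events=[tuple(e) for e in d["events"]],
            family_roles=d["family_roles"],
            n_proteins=d["n_proteins"],
            n_multidomain=d["n_multidomain"],
            n_proteins_with_insertion=d["n_proteins_with_insertion"],
            prevalence=d["prevalence"],
            depth_histogram={int(k): v for k, v in d["depth_histogram"].items()},
            seed=d.get("seed"),
            config=d.get("config", {}),
        )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Location/scale of a log-normal with the given arithmetic mean/sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_family_universe(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[SyntheticFamily]:
    """Draw the family universe: IDs, roles, architectures, size params.

    Family IDs use disjoint integer ranges per hierarchy level so that
    X/H/T-prefix parsing is exercised; families within the same synthetic
    H-group occur by construction (three T-groups per H, two H per X).
    A fraction of families is emitted as topology-only (ID ending ".0.0").
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    roles = list(config.role_propensity)
    probs = [config.role_propensity[r] for r in roles]
    h_mu, h_sig = _lognormal_params(config.host_length_mean, config.host_length_sd)
    i_mu, i_sig = _lognormal_params(config.insert_length_mean, config.insert_length_sd)
    families = []
    for i in range(config.n_families):
        x = 100 + i // 6
        h = 1 + (i % 6) // 3
        t = 1 + i % 3
        if rng.random() < config.p_tgroup_only:
            f_id = f"{x}.{h}.{500 + i}.0.0"
        else:
            f_id = f"{x}.{h}.{t}.{i + 1}"
        role = roles[int(rng.choice(len(roles), p=probs))]
        families.append(
            SyntheticFamily(
                f_id=f_id,
                role=role,
                architecture_label=str(rng.choice(ARCHITECTURE_LABELS)),
                host_log_mu=float(rng.normal(h_mu, 0.10)),
                insert_log_mu=float(rng.normal(i_mu, 0.10)),
                log_sigma=float((h_sig + i_sig) / 2.0),
            )
        )
    return families


def _draw_length(
    fam: SyntheticFamily, role: str, config: SyntheticConfig, rng: np.random.Generator
) -> int:
    if role == "insert":
        mu, lo = fam.insert_log_mu, config.min_insert_length
    else:
        mu, lo = fam.host_log_mu, config.min_host_length
    return max(lo, int(round(rng.lognormal(mu, fam.log_sigma))))


def generate_architectures(
    config: SyntheticConfig,
    families: list[SyntheticFamily] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProteinArchitecture], SyntheticGroundTruth]:
    """Generate a protein dataset from the insertion grammar, with truth.

    Each protein is a linear chain of domains; with probability
    ``p_insertion`` one chain domain (from a host-capable family) is
    interrupted by an insert (from an insert-capable family), recursing
    with probability ``p_nest`` up to ``max_depth`` and occasionally
    placing two side-by-side inserts in one gap.  Every generated gap is
    at least ``min_gap`` residues by construction.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if families is None:
        families = sample_family_universe(config, rng)
    host_fams = [f for f in families if f.role in HOST_CAPABLE]
    insert_fams = [f for f in families if f.role in INSERT_CAPABLE]
    # an insert that itself hosts a deeper insert must be role-versatile
    nest_host_fams = [f for f in families if f.role == "versatile"]
    any_fams = families

    truth = SyntheticGroundTruth(
        events=[],
        family_roles={f.f_id: f.role for f in families},
        seed=config.seed,
        config=asdict(config),
    )
    proteins: list[ProteinArchitecture] = []

    def pick(pool: list[SyntheticFamily]) -> SyntheticFamily:
        return pool[int(rng.integers(len(pool)))]

    for p_idx in range(config.n_proteins):
        pid = f"P{p_idx:06d}"
        uid_counter = [0]

        def new_uid() -> str:
            uid_counter[0] += 1
            return f"d{uid_counter[0]}"

        multidomain = rng.random() < config.p_multidomain
        n_chain = 2 + int(rng.poisson(config.multidomain_extra_mean)) if multidomain else 1
        with_insertion = multidomain and rng.random() < config.p_insertion

        domains: list[DomainInstance] = []
        protein_events: list[tuple[str, str, str, int]] = []
        cursor = 1

        def emit_insert_subtree(depth: int, host_uid: str) -> None:
            """Place 1 (or 2 side-by-side) inserts inside the current gap."""
            nonlocal cursor
            n_inserts = 2 if rng.random() < config.p_multi_insert else 1
            for j in range(n_inserts):
                if j > 0:
                    cursor += config.linker
                nest = (
                    depth < config.max_depth
                    and bool(nest_host_fams)
                    and rng.random() < config.p_nest
                )
                fam = pick(nest_host_fams if nest else insert_fams)
                uid = new_uid()
                length = _draw_length(fam, "insert", config, rng)
                if nest:
                    a1 = int(rng.integers(1, length))
                    seg1 = ResidueRange(cursor, cursor + a1 - 1)
                    cursor = seg1.end + 1 + config.linker
                    emit_insert_subtree(depth + 1, uid)
                    cursor += config.linker
                    seg2 = ResidueRange(cursor, cursor + (length - a1) - 1)
                    cursor = seg2.end + 1
                    segs: tuple[ResidueRange, ...] = (seg1, seg2)
                else:
                    segs = (ResidueRange(cursor, cursor + length - 1),)
                    cursor += length
                domains.append(
                    DomainInstance(pid, uid, fam.key, segs, fam.architecture_label)
                )
                protein_events.append((pid, host_uid, uid, depth))

        insert_at = int(rng.integers(n_chain)) if with_insertion else -1
        for c in range(n_chain):
            if c > 0:
                cursor += config.linker
            if c == insert_at:
                fam = pick(host_fams)
                uid = new_uid()
                length = _draw_length(fam, "host", config, rng)
                a1 = int(rng.integers(1, length))
                seg1 = ResidueRange(cursor, cursor + a1 - 1)
                cursor = seg1.end + 1 + config.linker
                emit_insert_subtree(1, uid)
                cursor += config.linker
                seg2 = ResidueRange(cursor, cursor + (length - a1) - 1)
                cursor = seg2.end + 1
                domains.append(
                    DomainInstance(pid, uid, fam.key, (seg1, seg2), fam.architecture_label)
                )
            else:
                fam = pick(any_fams)
                uid = new_uid()
                length = _draw_length(fam, "host", config, rng)
                domains.append(
                    DomainInstance(
                        pid, uid, fam.key,
                        (ResidueRange(cursor, cursor + length - 1),),
                        fam.architecture_label,
                    )
                )
                cursor += length

        proteins.append(ProteinArchitecture(pid, domains))
        truth.events.extend(protein_events)
        truth.n_proteins += 1
        if multidomain:
            truth.n_multidomain += 1
        if protein_events:
            truth.n_proteins_with_insertion += 1
            dmax = max(d for _, _, _, d in protein_events)
            truth.depth_histogram[dmax] = truth.depth_histogram.get(dmax, 0) + 1

    truth.prevalence = (
        truth.n_proteins_with_insertion / truth.n_multidomain
        if truth.n_multidomain
        else 0.0
    )
    truth.depth_histogram = dict(sorted(truth.depth_histogram.items()))
    return proteins, truth


def _arc_trace(n: int, target: float, spacing: float) -> np.ndarray:
    """n points with consecutive spacing ``spacing`` whose end-to-end
    distance equals ``target`` (clamped to the reachable range), laid on a
    circular arc in the xy-plane."""
    if n == 1:
        return np.zeros((1, 3))
    straight = (n - 1) * spacing
    d = min(max(target, 1e-3), straight)
    if math.isclose(d, straight, rel_tol=1e-9):
        return np.column_stack(
            [np.arange(n) * spacing, np.zeros(n), np.zeros(n)]
        )

    # radius R such that (n-1) steps of chord `spacing` subtend an
    # end-to-end chord of d; total angle kept below one full turn
    def endpoint_gap(radius: float) -> float:
        delta = 2.0 * math.asin(spacing / (2.0 * radius))
        total = (n - 1) * delta
        return 2.0 * radius * abs(math.sin(total / 2.0)) - d

    r_min = spacing / (2.0 * math.sin(math.pi / (n - 1))) if n > 2 else spacing / 2.0
    r_min *= 1.0 + 1e-12
    r_max = spacing * n * 1e6
    radius = brentq(endpoint_gap, r_min, r_max, xtol=1e-10)
    delta = 2.0 * math.asin(spacing / (2.0 * radius))
    angles = np.arange(n) * delta
    pts = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)]
    )
    return pts - pts[0]


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q, rng.normal(scale=50.0, size=3)


def generate_toy_traces(
    config: SyntheticConfig,
    proteins: list[ProteinArchitecture],
    truth: SyntheticGroundTruth,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str], CaTrace]:
    """Per-domain toy Cα traces with role-appropriate termini distances.

    Domains appearing as inserts in the ground truth draw their
    first-to-last-residue distance from the insert distribution
    (log-normal around ``insert_termini_median``); all other domains draw
    from the background distribution.  Consecutive Cα spacing is
    ``ca_spacing`` (~3.8 Å); each trace gets a random rigid placement,
    which leaves the termini distance unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    insert_uids = {(p, i) for p, _, i, _ in truth.events}
    traces: dict[tuple[str, str], CaTrace] = {}
    for prot in proteins:
        for d in prot.domains:
            is_insert = (prot.protein_id, d.domain_uid) in insert_uids
            median = (
                config.insert_termini_median if is_insert
                else config.background_termini_median
            )
            sigma = (
                config.insert_termini_sigma if is_insert
                else config.background_termini_sigma
            )
            target = float(rng.lognormal(math.log(median), sigma))
            residues = np.concatenate(
                [np.arange(s.start, s.end + 1) for s in d.segments]
            )
            pts = _arc_trace(len(residues), target, config.ca_spacing)
            rot, trans = _random_rigid(rng)
            traces[(prot.protein_id, d.domain_uid)] = CaTrace(
                f"{prot.protein_id}_{d.domain_uid}", residues, pts @ rot.T + trans
            )
    return traces


def make_nested_protein(
    levels: int,
    innermost_length: int = 60,
    flank: int = 60,
    linker: int = 2,
    protein_id: str = "NEST",
) -> ProteinArchitecture:
    """Strictly nested architecture with ``levels`` insertion levels.

    Builds ``levels + 1`` domains: an innermost continuous domain wrapped
    by successive two-segment hosts, each flank ``flank`` residues, so
    every gap comfortably exceeds the 30-residue detection threshold and
    the protein's maximum nesting depth equals ``levels``.
    """
    if levels < 0:
        raise ConfigError("levels must be >= 0")
    # innermost domain is depth `levels`; wrap outward
    total_inner = innermost_length
    spans: list[int] = [total_inner]
    for _ in range(levels):
        total_inner = flank + linker + total_inner + linker + flank
        spans.append(total_inner)
    domains: list[DomainInstance] = []
    offset = 1
    for i in range(levels + 1):  # i = depth of this domain's insert event host chain
        uid = f"d{i + 1}"
        fam = FamilyKey(f"{100 + i}.1.1.1")
        inner_span = spans[levels - i - 1] if i < levels else 0
        if i < levels:
            seg1 = ResidueRange(offset, offset + flank - 1)
            a2_start = seg1.end + 1 + linker + inner_span + linker
            seg2 = ResidueRange(a2_start, a2_start + flank - 1)
            domains.append(DomainInstance(protein_id, uid, fam, (seg1, seg2)))
            offset = seg1.end + 1 + linker
        else:
            domains.append(
                DomainInstance(
                    protein_id, uid, fam,
                    (ResidueRange(offset, offset + innermost_length - 1),),
                )
            )
    return ProteinArchitecture(protein_id, domains)


def _mk(pid: str, specs: list[tuple[str, str, list[tuple[int, int]]]]) -> ProteinArchitecture:
    return ProteinArchitecture(
        pid,
        [
            DomainInstance(
                pid, uid, FamilyKey(f_id),
                tuple(ResidueRange(a, b) for a, b in segs),
            )
            for uid, f_id, segs in specs
        ],
    )


def generate_adversarial(min_gap: int = 30) -> tuple[
    list[ProteinArchitecture], set[tuple[str, str, str]]
]:
    """Hand-constructed edge-case proteins with hand-derived truth.

    Covers gaps of exactly min_gap-1 / min_gap / min_gap+1, a tight nest
    with nearly equal containing gaps, two side-by-side inserts in one gap, a
    discontinuous insert inside one gap, a discontinuous domain straddling
    two gaps (no event), and an A1-B1-C-B2-A2 nest.  Truth follows the
    smallest-gap exclusive-assignment rule with ties broken by gap start
    then host uid.
    """
    g = min_gap
    proteins = [
        # gap of g-1: below threshold, no event (insert would not fit anyway;
        # gap contains no domain)
        _mk("ADV_below", [("dA", "100.1.1.1", [(1, 100), (100 + g, 199 + g)]),
                          ("dB", "200.1.1.1", [(200 + g, 299 + g)])]),
        # gap exactly g, insert fills it completely: one event
        _mk("ADV_at", [("dA", "100.1.1.1", [(1, 100), (101 + g, 200 + g)]),
                       ("dB", "200.1.1.1", [(101, 100 + g)])]),
        # gap g+1 with the insert one residue short of the gap end
        _mk("ADV_above", [("dA", "100.1.1.1", [(1, 100), (102 + g, 201 + g)]),
                          ("dB", "200.1.1.1", [(101, 100 + g)])]),
        # tight nest: C contained in two gaps of nearly equal length
        # (120 vs 100) and must go to the smaller; equal-length containing
        # gaps are impossible for disjoint domains (inner gap is always
        # strictly smaller), so near-ties are the hardest reachable case
        _mk("ADV_tight", [("dA", "100.1.1.1", [(1, 40), (161, 200)]),
                          ("dB", "200.1.1.1", [(41, 50), (151, 160)]),
                          ("dC", "300.1.1.1", [(51, 150)])]),
        # two side-by-side inserts in one gap
        _mk("ADV_side", [("dA", "100.1.1.1", [(1, 100), (301, 400)]),
                         ("dB", "200.1.1.1", [(101, 180)]),
                         ("dC", "300.1.1.1", [(201, 300)])]),
        # discontinuous insert entirely within one gap
        _mk("ADV_disc", [("dA", "100.1.1.1", [(1, 100), (301, 400)]),
                         ("dB", "200.1.1.1", [(101, 150), (201, 300)])]),
        # discontinuous domain straddling two gaps of dA: no event
        _mk("ADV_straddle", [("dA", "100.1.1.1", [(1, 100), (201, 300), (401, 500)]),
                             ("dB", "200.1.1.1", [(101, 200), (301, 400)])]),
        # nested A1-B1-C-B2-A2
        _mk("ADV_nest", [("dA", "100.1.1.1", [(1, 100), (331, 430)]),
                         ("dB", "200.1.1.1", [(101, 180), (251, 330)]),
                         ("dC", "300.1.1.1", [(181, 250)])]),
    ]
    truth = {
        ("ADV_at", "dA", "dB"),
        ("ADV_above", "dA", "dB"),
        ("ADV_tight", "dA", "dB"),
        ("ADV_tight", "dB", "dC"),
        ("ADV_side", "dA", "dB"),
        ("ADV_side", "dA", "dC"),
        ("ADV_disc", "dA", "dB"),
        ("ADV_nest", "dA", "dB"),
        ("ADV_nest", "dB", "dC"),
    }
    return proteins, truth
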