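"""Surface patches, distance-dependent weights and the DBPSite feature set.

For each surface residue (the central residue), the L spatially nearest
surface residues of the same chain, measured between alpha carbons,
constitute its surface patch (L = 25 by default).  Every patch member i at
distance d_i from the centre receives a weighting factor w_i in (0, 1]
that decreases with distance and equals 1 for the centre itself; patch
features are weighted averages sum(w_i x_i) / sum(w_i).

The full feature vector of a residue has 43 dimensions:

* RW-PSSM (40): the central residue's 20 logistic-scaled PSSM log-odds,
  followed by 20 weighted averages of the scaled PSSM columns over the
  patch neighbours;
* WIP (1): weighted average interface propensity over the patch;
* WBC (1): weighted average betweenness centrality over the patch;
* ScASA (1): the central residue's raw side-chain ASA.

The alternative C-PSSM encoding concatenates the scaled PSSM rows of all
patch members in distance order (20 * L values).

The interface propensity of amino-acid type a is the log2 odds ratio of
its frequency among DNA-binding versus nonbinding surface residues, with
a symmetric pseudocount; positive values mark interface-enriched types.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .structure import Residue, THREE_TO_ONE

__all__ = [
    "AA_ORDER",
    "DEFAULT_PATCH_SIZE",
    "WEIGHT_SCHEMES",
    "weighting_factor",
    "PssmProfile",
    "read_pssm",
    "write_pssm",
    "scale_pssm",
    "SurfacePatch",
    "build_surface_patch",
    "rw_pssm",
    "c_pssm",
    "PropensityTable",
    "interface_propensity_table",
    "weighted_scalar_feature",
    "FeatureVector",
    "assemble_feature_vector",
    "feature_names",
    "FEATURE_SETS",
    "select_feature_subset",
]

#: PSI-BLAST column order of the 20 amino-acid types.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

DEFAULT_PATCH_SIZE = 25

ResidueKey = tuple[str, int, str]


# ---------------------------------------------------------------------------
# Weighting factor
# ---------------------------------------------------------------------------

def _reciprocal(d: np.ndarray, **_: float) -> np.ndarray:
    return 1.0 / (1.0 + d)


def _exponential(d: np.ndarray, sigma: float = 5.0, **_: float) -> np.ndarray:
    return np.exp(-d / sigma)


def _linear(d: np.ndarray, d_max: float = 50.0, **_: float) -> np.ndarray:
    if np.any(d >= d_max):
        raise ValueError(f"linear weighting undefined at d >= d_max ({d_max} A)")
    return 1.0 - d / d_max


#: Shipped weighting functions; each maps distance (A) to a weight in
#: (0, 1], equal to 1 at d = 0 and strictly decreasing.
WEIGHT_SCHEMES: dict[str, Callable[..., np.ndarray]] = {
    "reciprocal": _reciprocal,
    "exponential": _exponential,
    "linear": _linear,
}

DEFAULT_WEIGHT_SCHEME = "reciprocal"


def weighting_factor(
    d: float | np.ndarray, scheme: str = DEFAULT_WEIGHT_SCHEME, **params: float
) -> float | np.ndarray:
    """Distance-dependent contribution weight of a patch residue.

    ``d`` is the Calpha distance (A) to the central residue; the central
    residue itself (d = 0) has the maximum weight 1.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise KeyError(f"unknown weighting scheme {scheme!r}; shipped: {sorted(WEIGHT_SCHEMES)}")
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distance must be non-negative")
    out = WEIGHT_SCHEMES[scheme](arr, **params)
    return float(out) if np.isscalar(d) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# PSSM profiles
# ---------------------------------------------------------------------------

@dataclass
class PssmProfile:
    """Per-residue PSSM log-odds rows aligned to chain residues.

    ``matrix`` is (n_residues, 20) in PSI-BLAST column order; ``sequence``
    holds the one-letter codes from the profile; ``keys`` aligns rows to
    structure residue keys once attached.
    """

    matrix: np.ndarray
    sequence: str
    keys: list[ResidueKey] | None = None
    scaled: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("PSSM matrix must have exactly 20 columns")
        if len(self.sequence) != self.matrix.shape[0]:
            raise ValueError("sequence length must match matrix rows")

    def row(self, key: ResidueKey) -> np.ndarray:
        if self.keys is None:
            raise ValueError("profile is not aligned to structure residues")
        try:
            return self.matrix[self.keys.index(key)]
        except ValueError:
            raise KeyError(f"no PSSM row for residue {key}") from None

    def attach(self, residues: Sequence[Residue]) -> "PssmProfile":
        """Align rows to residues by order, checking one-letter codes."""
        if len(residues) != self.matrix.shape[0]:
            raise ValueError(
                f"profile has {self.matrix.shape[0]} rows but chain has "
                f"{len(residues)} residues"
            )
        for res, letter in zip(residues, self.sequence):
            if res.one_letter != "X" and letter != "X" and res.one_letter != letter:
                raise ValueError(
                    f"sequence mismatch at {res.label()}: structure "
                    f"{res.one_letter!r} vs profile {letter!r}"
                )
        return PssmProfile(
            matrix=self.matrix,
            sequence=self.sequence,
            keys=[r.key for r in residues],
            scaled=self.scaled,
        )


_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Z])\s+(-?\d)")


def read_pssm(text: str) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm``).

    Only the first 20 numeric columns (the log-odds block) are read.
    """
    rows = []
    letters = []
    for line in text.splitlines():
        if not _PSSM_ROW.match(line):
            continue
        parts = line.split()
        values = parts[2:22]
        if len(values) < 20:
            raise ValueError(f"PSSM row has fewer than 20 scores: {line!r}")
        letters.append(parts[1])
        rows.append([float(v) for v in values])
    if not rows:
        raise ValueError("no PSSM rows found in stream")
    return PssmProfile(matrix=np.array(rows), sequence="".join(letters))


def write_pssm(profile: PssmProfile) -> str:
    """Serialize a raw profile in PSI-BLAST ASCII layout (integer scores)."""
    if profile.scaled:
        raise ValueError("write raw (unscaled) profiles only")
    header = "    " + "  ".join(AA_ORDER) + "  " + "  ".join(AA_ORDER)
    lines = ["", "Last position-specific scoring matrix computed", header]
    for i, (letter, row) in enumerate(zip(profile.sequence, profile.matrix), start=1):
        ints = " ".join(f"{int(round(v)):3d}" for v in row)
        # pad the weighted-percentage block with zeros for layout parity
        lines.append(f"{i:5d} {letter} {ints} " + " ".join(["  0"] * 20))
    return "\n".join(lines) + "\n"


def scale_pssm(profile: PssmProfile) -> PssmProfile:
    """Logistic-scale log-odds elementwise to (0, 1): x -> 1/(1 + e^-x)."""
    return PssmProfile(
        matrix=1.0 / (1.0 + np.exp(-profile.matrix)),
        sequence=profile.sequence,
        keys=profile.keys,
        scaled=True,
    )


# ---------------------------------------------------------------------------
# Surface patches
# ---------------------------------------------------------------------------

@dataclass
class SurfacePatch:
    central: ResidueKey
    members: list[ResidueKey]       # central first, then ascending distance
    member_names: list[str]         # parent 3-letter codes, same order
    distances: np.ndarray           # A, d[0] == 0
    weights: np.ndarray             # w[0] == 1

    @property
    def size(self) -> int:
        return len(self.members)


def build_surface_patch(
    central: Residue,
    surface_residues: Sequence[Residue],
    L: int = DEFAULT_PATCH_SIZE,
    scheme: str = DEFAULT_WEIGHT_SCHEME,
    **scheme_params: float,
) -> SurfacePatch:
    """Patch of ``central`` plus its L-1 nearest surface residues.

    Distances are between alpha carbons within the same chain; ties are
    broken by ascending sequence index (then insertion code).  If fewer
    than L surface residues exist, all are used.
    """
    if L < 1:
        raise ValueError("patch size L must be >= 1")
    keys = {r.key for r in surface_residues}
    if central.key not in keys:
        raise ValueError(f"central residue {central.label()} is not a surface residue")
    c = central.ca_coord
    if c is None:
        raise ValueError(f"central residue {central.label()} lacks CA")
    scored = []
    for res in surface_residues:
        if res.key == central.key:
            continue
        ca = res.ca_coord
        if ca is None:
            continue
        d = float(np.linalg.norm(ca - c))
        scored.append((d, res.seq_index, res.ins_code, res))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    chosen = scored[: L - 1]
    members = [central] + [t[3] for t in chosen]
    distances = np.array([0.0] + [t[0] for t in chosen])
    weights = weighting_factor(distances, scheme=scheme, **scheme_params)
    return SurfacePatch(
        central=central.key,
        members=[r.key for r in members],
        member_names=[r.parent_name for r in members],
        distances=distances,
        weights=np.asarray(weights, dtype=float),
    )


# ---------------------------------------------------------------------------
# PSSM patch encodings
# ---------------------------------------------------------------------------

def rw_pssm(patch: SurfacePatch, profile: PssmProfile) -> np.ndarray:
    """Reduced weighted PSSM encoding: 40 values for any patch size.

    First 20: the central residue's scaled row.  Last 20: for each
    amino-acid type a, F_a = sum_i w_i M_{s(i),a} / sum_i w_i over the
    patch neighbours (centre excluded; zero when the patch has no
    neighbours).
    """
    if not profile.scaled:
        raise ValueError("profile must be logistic-scaled first")
    central_row = profile.row(patch.central)
    if patch.size == 1:
        return np.concatenate([central_row, np.zeros(20)])
    rows = np.stack([profile.row(k) for k in patch.members[1:]])
    w = patch.weights[1:]
    averaged = (w[:, None] * rows).sum(axis=0) / w.sum()
    return np.concatenate([central_row, averaged])


def c_pssm(patch: SurfacePatch, profile: PssmProfile, L: int) -> np.ndarray:
    """Concatenated PSSM encoding: the members' scaled rows in patch order,
    zero-padded to exactly 20 * L values."""
    if not profile.scaled:
        raise ValueError("profile must be logistic-scaled first")
    rows = [profile.row(k) for k in patch.members[:L]]
    flat = np.concatenate(rows) if rows else np.empty(0)
    out = np.zeros(20 * L)
    out[: flat.size] = flat
    return out


# ---------------------------------------------------------------------------
# Interface propensity
# ---------------------------------------------------------------------------

@dataclass
class PropensityTable:
    values: dict[str, float]            # one-letter type -> IP_a
    counts: dict[str, tuple[int, int]]  # type -> (N_Ba, N_NBa)
    n_binding: int
    n_nonbinding: int
    pseudocount: float

    def of(self, residue_name: str) -> float:
        letter = THREE_TO_ONE.get(residue_name, residue_name)
        if letter not in self.values:
            raise KeyError(f"no propensity for residue type {residue_name!r}")
        return self.values[letter]


def interface_propensity_table(
    labeled_residues: Sequence[tuple[str, str]],
    pseudocount: float = 1.0,
) -> PropensityTable:
    """Interface propensities from labeled surface residues.

    ``labeled_residues`` are ``(three_letter_name, label)`` pairs with
    label ``binding`` or ``nonbinding``.  For type a,

        IP_a = log2( ((N_Ba + psi) / (N_B + 20 psi))
                   / ((N_NBa + psi) / (N_NB + 20 psi)) )

    with symmetric pseudocount psi.  Positive values mean the type occurs
    more frequently at DNA-binding interfaces than on the remaining
    surface.
    """
    nb: dict[str, int] = {a: 0 for a in AA_ORDER}
    nnb: dict[str, int] = {a: 0 for a in AA_ORDER}
    for name, label in labeled_residues:
        letter = THREE_TO_ONE.get(name, None)
        if letter is None:
            continue
        if label == "binding":
            nb[letter] += 1
        elif label == "nonbinding":
            nnb[letter] += 1
    n_b = sum(nb.values())
    n_nb = sum(nnb.values())
    if n_b == 0 or n_nb == 0:
        raise ValueError("need at least one binding and one nonbinding residue")
    psi = pseudocount
    values = {
        a: math.log2(
            ((nb[a] + psi) / (n_b + 20 * psi)) / ((nnb[a] + psi) / (n_nb + 20 * psi))
        )
        for a in AA_ORDER
    }
    return PropensityTable(
        values=values,
        counts={a: (nb[a], nnb[a]) for a in AA_ORDER},
        n_binding=n_b,
        n_nonbinding=n_nb,
        pseudocount=psi,
    )


# ---------------------------------------------------------------------------
# Weighted scalar patch features (WBC, WIP, WScASA)
# ---------------------------------------------------------------------------

def weighted_scalar_feature(
    patch: SurfacePatch, values: Mapping[ResidueKey, float]
) -> float:
    """Weighted average of a per-residue scalar over ALL patch members
    (central residue included): sum(w_i x_i) / sum(w_i)."""
    try:
        x = np.array([values[k] for k in patch.members], dtype=float)
    except KeyError as exc:
        raise KeyError(f"missing value for patch residue {exc.args[0]}") from None
    return float((patch.weights * x).sum() / patch.weights.sum())


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

FEATURE_SETS = {
    "full": ("rw_pssm", "wip", "wbc", "sc_asa"),
    "no_rw_pssm": ("wip", "wbc", "sc_asa"),
    "no_wip": ("rw_pssm", "wbc", "sc_asa"),
    "no_wbc": ("rw_pssm", "wip", "sc_asa"),
    "no_sc_asa": ("rw_pssm", "wip", "wbc"),
}

_BLOCK_SIZES = {"rw_pssm": 40, "wip": 1, "wbc": 1, "sc_asa": 1}


@dataclass
class FeatureVector:
    key: ResidueKey
    values: np.ndarray
    names: list[str]
    encoding: str = "full"


def feature_names(feature_set: str = "full") -> list[str]:
    names = []
    for block in FEATURE_SETS[feature_set]:
        if block == "rw_pssm":
            names += [f"pssm_c_{a}" for a in AA_ORDER]
            names += [f"pssm_w_{a}" for a in AA_ORDER]
        else:
            names.append(block)
    return names


def assemble_feature_vector(
    patch: SurfacePatch,
    profile: PssmProfile,
    propensities: PropensityTable,
    betweenness: Mapping[ResidueKey, float],
    sc_asa: Mapping[ResidueKey, float],
    feature_set: str = "full",
) -> FeatureVector:
    """The DBPSite input vector for one central residue.

    The full set is [RW-PSSM (40), WIP, WBC, ScASA] = 43 values; ScASA is
    the central residue's own raw side-chain ASA.  Leave-one-out subsets
    (for ablation) drop the corresponding block.
    """
    ip_values = {
        k: propensities.values[THREE_TO_ONE.get(name, "X")]
        for k, name in zip(patch.members, patch.member_names)
        if THREE_TO_ONE.get(name, "X") in propensities.values
    }
    blocks = {
        "rw_pssm": lambda: rw_pssm(patch, profile),
        "wip": lambda: np.array([weighted_scalar_feature(patch, ip_values)]),
        "wbc": lambda: np.array([weighted_scalar_feature(patch, betweenness)]),
        "sc_asa": lambda: np.array([sc_asa[patch.central]]),
    }
    parts = [blocks[b]() for b in FEATURE_SETS[feature_set]]
    return FeatureVector(
        key=patch.central,
        values=np.concatenate(parts),
        names=feature_names(feature_set),
        encoding=feature_set,
    )


def select_feature_subset(
    full_matrix: np.ndarray, feature_set: str
) -> np.ndarray:
    """Columns of a full (n, 43) matrix for a leave-one-out feature set."""
    full_names = feature_names("full")
    wanted = set(feature_names(feature_set))
    cols = [i for i, nm in enumerate(full_names) if nm in wanted]
    return full_matrix[:, cols]
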