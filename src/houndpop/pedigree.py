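"""Genealogical analytics: inbreeding, relatedness, completeness, Ne, founders.

The inbreeding coefficient F is Wright's probability of autozygosity,
computed by the Meuwissen-Luo algorithm (tracing the dummy-progeny row of
the Cholesky factor of the numerator relationship matrix A, so no dense A is
ever materialized). Average relatedness AR_i is the mean of row i of A over
all individuals, obtained with Colleau's indirect method in O(n).

The realized effective population size follows the individual-increase
approach: dF_i = 1 - (1 - F_i)^(1/(t_i - 1)) with t_i the individual's
equivalent complete generations, and Ne = 1/(2 * mean dF).

Founder statistics: the effective number of founders f_e = 1/sum q_k^2 from
expected founder contributions q_k to a reference population, and the
effective number of ancestors f_a = 1/sum p_k^2 from marginal contributions
of ancestors chosen greedily (Boichard's algorithm). f_a <= f_e, and their
ratio flags historical bottlenecks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = -1
_UNKNOWN_TOKENS = {"", "0", "na", "nan", "none", "unknown", "."}


class PedigreeError(ValueError):
    pass


class PedigreeTable:
    """Topologically ordered pedigree: parents always precede offspring.

    Attributes
    ----------
    ids : list of individual identifiers in topological order
    sire, dam : int arrays of parent indices (UNKNOWN = -1)
    sex : array of 'male'/'female'/'unknown'
    birthdate : array of pandas Timestamps (NaT when absent)
    """

    def __init__(self, ids, sire, dam, sex=None, birthdate=None):
        self.ids = list(ids)
        self.sire = np.asarray(sire, dtype=int)
        self.dam = np.asarray(dam, dtype=int)
        n = len(self.ids)
        self.sex = (
            np.asarray(sex) if sex is not None else np.array(["unknown"] * n)
        )
        self.birthdate = (
            pd.to_datetime(pd.Series(birthdate))
            if birthdate is not None
            else pd.Series([pd.NaT] * n)
        )
        self.index = {ind: i for i, ind in enumerate(self.ids)}
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and p >= i:
                    raise PedigreeError("table is not topologically ordered")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def founders(self) -> np.ndarray:
        """Indices of individuals with both parents unknown."""
        return np.flatnonzero((self.sire == UNKNOWN) & (self.dam == UNKNOWN))

    def offspringless(self) -> np.ndarray:
        """Indices of individuals that are nobody's parent (default reference)."""
        is_parent = np.zeros(self.n, dtype=bool)
        for p in np.concatenate([self.sire, self.dam]):
            if p != UNKNOWN:
                is_parent[p] = True
        return np.flatnonzero(~is_parent)

    def ancestors_of(self, idx: int) -> set[int]:
        out: set[int] = set()
        stack = [idx]
        while stack:
            i = stack.pop()
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and p not in out:
                    out.add(p)
                    stack.append(p)
        return out


def _normalize_parent(value) -> object:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return None if text.lower() in _UNKNOWN_TOKENS else text


def validate_pedigree(table: pd.DataFrame) -> PedigreeTable:
    """Check and canonicalize a raw (id, sire, dam[, sex, birthdate]) table.

    Unknown parents (0, empty, NA) normalize to UNKNOWN; rows are placed in
    topological order. Cycles raise naming a member; an individual appearing
    both as sire and dam raises a sex-conflict error; birthdates later than
    an offspring's are warnings (kennel records are messy), not errors.
    """
    df = table.copy()
    df.columns = [c.lower() for c in df.columns]
    ids = [str(x).strip() for x in df["id"]]
    if len(set(ids)) != len(ids):
        raise PedigreeError("duplicate ids in pedigree")
    sires = [_normalize_parent(x) for x in df.get("sire", [None] * len(ids))]
    dams = [_normalize_parent(x) for x in df.get("dam", [None] * len(ids))]
    known = set(ids)
    for parents in (sires, dams):
        for k, p in enumerate(parents):
            if p is not None and p not in known:
                # parent referenced but not listed: add as founder
                ids.append(p)
                sires.append(None)
                dams.append(None)
                known.add(p)
    as_sire = {p for p in sires if p is not None}
    as_dam = {p for p in dams if p is not None}
    both = as_sire & as_dam
    if both:
        raise PedigreeError(
            f"individual(s) used as both sire and dam: {sorted(both)[:5]}"
        )

    # Kahn topological sort (child depends on parents)
    pos = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sires[i], dams[i]):
            if p is not None:
                children[pos[p]].append(i)
                indeg[i] += 1
    order: list[int] = []
    queue = [i for i in range(n) if indeg[i] == 0]
    while queue:
        queue.sort(key=lambda k: ids[k])  # canonical order independent of row order
        i = queue.pop(0)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        member = ids[next(i for i in range(n) if indeg[i] > 0)]
        raise PedigreeError(f"pedigree contains a cycle involving {member!r}")

    new_pos = {old: new for new, old in enumerate(order)}
    ids_sorted = [ids[i] for i in order]
    sire_idx = np.full(n, UNKNOWN)
    dam_idx = np.full(n, UNKNOWN)
    for new_i, old_i in enumerate(order):
        if sires[old_i] is not None:
            sire_idx[new_i] = new_pos[pos[sires[old_i]]]
        if dams[old_i] is not None:
            dam_idx[new_i] = new_pos[pos[dams[old_i]]]

    sex_col = df["sex"] if "sex" in df else pd.Series(["unknown"] * len(df))
    sex_map = {str(i).strip(): str(s).strip().lower() for i, s in zip(df["id"], sex_col)}
    sex = np.array([sex_map.get(ind, "unknown") for ind in ids_sorted])
    sex[~np.isin(sex, ("male", "female"))] = "unknown"
    for i in range(n):
        s = sire_idx[i]
        d = dam_idx[i]
        if s != UNKNOWN and sex[s] == "female":
            raise PedigreeError(f"sire {ids_sorted[s]!r} recorded as female")
        if d != UNKNOWN and sex[d] == "male":
            raise PedigreeError(f"dam {ids_sorted[d]!r} recorded as male")
    # fill in sexes implied by parental roles
    for i in range(n):
        if sire_idx[i] != UNKNOWN:
            sex[sire_idx[i]] = "male"
        if dam_idx[i] != UNKNOWN:
            sex[dam_idx[i]] = "female"

    if "birthdate" in df:
        bd_map = dict(zip((str(i).strip() for i in df["id"]), df["birthdate"]))
        birth = pd.to_datetime(
            pd.Series([bd_map.get(ind) for ind in ids_sorted]), errors="coerce"
        )
        for i in range(n):
            for p in (sire_idx[i], dam_idx[i]):
                if (
                    p != UNKNOWN
                    and pd.notna(birth[i])
                    and pd.notna(birth[p])
                    and birth[p] > birth[i]
                ):
                    warnings.warn(
                        f"parent {ids_sorted[p]} born after offspring {ids_sorted[i]}",
                        stacklevel=2,
                    )
    else:
        birth = pd.Series([pd.NaT] * n)
    return PedigreeTable(ids_sorted, sire_idx, dam_idx, sex, birth)


def read_pedigree(path, sep=None) -> PedigreeTable:
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    return validate_pedigree(df)


# ---------------------------------------------------------------------------
# Inbreeding (Meuwissen & Luo) and relatedness
# ---------------------------------------------------------------------------

def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Wright's F for every individual via the Meuwissen-Luo trace.

    For individual i with parents s, d the row of a dummy progeny in the
    Cholesky factor L of A is traced back through the pedigree, giving
    F_i = sum_j L_j^2 D_j - 1 exactly; founders have F = 0.
    """
    n = ped.n
    F = np.zeros(n)
    D = np.zeros(n)  # Mendelian sampling variance given parental F
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        fs = F[s] if s != UNKNOWN else -1.0
        fd = F[d] if d != UNKNOWN else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
            continue
        w = np.zeros(i)
        w[s] += 0.5
        w[d] += 0.5
        acc = 0.0
        for j in range(i - 1, -1, -1):
            wj = w[j]
            if wj == 0.0:
                continue
            acc += wj * wj * D[j]
            if ped.sire[j] != UNKNOWN:
                w[ped.sire[j]] += 0.5 * wj
            if ped.dam[j] != UNKNOWN:
                w[ped.dam[j]] += 0.5 * wj
        F[i] = D[i] + acc - 1.0  # dummy progeny diagonal minus one
    return F


def relationship_matrix(ped: PedigreeTable) -> np.ndarray:
    """Dense numerator relationship matrix A (tabular method). O(n^2) memory;
    intended for moderate pedigrees and as a cross-check."""
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        a_sd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            val = 0.0
            if s != UNKNOWN:
                val += 0.5 * A[j, s]
            if d != UNKNOWN:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A


def average_relatedness(ped: PedigreeTable) -> np.ndarray:
    """AR_i = mean_j a_ij (row means of A, self included), as a fraction.

    Uses Colleau's indirect method: with A = L D L' (L = (I - 0.5 P)^{-1}),
    A v is computed by one backward and one forward sweep, never forming A.
    """
    n = ped.n
    F = inbreeding(ped)
    D = np.empty(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        fs = F[s] if s != UNKNOWN else -1.0
        fd = F[d] if d != UNKNOWN else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
    v = np.full(n, 1.0 / n)
    # y = L' v  (reverse order: each individual passes half its weight up)
    y = v.copy()
    for i in range(n - 1, -1, -1):
        if ped.sire[i] != UNKNOWN:
            y[ped.sire[i]] += 0.5 * y[i]
        if ped.dam[i] != UNKNOWN:
            y[ped.dam[i]] += 0.5 * y[i]
    z = D * y
    # w = L z  (forward order: each individual receives half of each parent)
    w = z.copy()
    for i in range(n):
        if ped.sire[i] != UNKNOWN:
            w[i] += 0.5 * w[ped.sire[i]]
        if ped.dam[i] != UNKNOWN:
            w[i] += 0.5 * w[ped.dam[i]]
    return w


# ---------------------------------------------------------------------------
# Pedigree completeness
# ---------------------------------------------------------------------------

def completeness(ped: PedigreeTable) -> pd.DataFrame:
    """Per-individual (gen_max, gen_complete, gen_equiv).

    gen_max: longest known-ancestor path. gen_complete: deepest g with all
    2^g ancestors known at depths 1..g. gen_equiv: sum over known-ancestor
    paths of (1/2)^depth.
    """
    n = ped.n
    gen_max = np.zeros(n, dtype=int)
    gen_complete = np.zeros(n, dtype=int)
    gen_equiv = np.zeros(n)
    for i in range(n):  # parents precede offspring, so plain loops suffice
        s, d = ped.sire[i], ped.dam[i]
        gm = []
        if s != UNKNOWN:
            gm.append(1 + gen_max[s])
            gen_equiv[i] += 0.5 * (1 + gen_equiv[s])
        if d != UNKNOWN:
            gm.append(1 + gen_max[d])
            gen_equiv[i] += 0.5 * (1 + gen_equiv[d])
        gen_max[i] = max(gm, default=0)
        if s != UNKNOWN and d != UNKNOWN:
            gen_complete[i] = 1 + min(gen_complete[s], gen_complete[d])
    return pd.DataFrame(
        {
            "id": ped.ids,
            "gen_max": gen_max,
            "gen_complete": gen_complete,
            "gen_equiv": gen_equiv,
        }
    )


# ---------------------------------------------------------------------------
# dF and realized Ne
# ---------------------------------------------------------------------------

def delta_f_and_ne(F: np.ndarray, gen_equiv: np.ndarray) -> tuple[float, float]:
    """Mean individual inbreeding rate and realized Ne = 1/(2 dF).

    dF_i = 1 - (1 - F_i)^(1/(t_i - 1)) over individuals with gen_equiv > 1;
    dF = 0 maps to an infinite Ne.
    """
    F = np.asarray(F, dtype=float)
    t = np.asarray(gen_equiv, dtype=float)
    eligible = t > 1
    if not eligible.any():
        raise PedigreeError("no individual with equivalent generations > 1")
    df_i = 1 - (1 - F[eligible]) ** (1.0 / (t[eligible] - 1))
    delta_f = float(df_i.mean())
    ne = math.inf if delta_f == 0 else 1.0 / (2 * delta_f)
    return delta_f, ne


def delta_f_regression(F: np.ndarray, gen_equiv: np.ndarray) -> float:
    """Alternative dF: slope of F regressed on equivalent generations."""
    t = np.asarray(gen_equiv, dtype=float)
    slope = np.polyfit(t, np.asarray(F, dtype=float), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Founder statistics (f_e, and Boichard's f_a)
# ---------------------------------------------------------------------------

def _expected_contributions(
    ped: PedigreeTable,
    reference: np.ndarray,
    blocked: set[int] | None = None,
) -> np.ndarray:
    """Expected genetic contribution of every individual to the reference.

    One upward sweep: each reference member starts with weight 1/|ref|; an
    individual passes half its accumulated weight to each known parent.
    Members of ``blocked`` keep their weight but pass nothing upward
    (their parent links are cut).
    """
    blocked = blocked or set()
    c = np.zeros(ped.n)
    ref_w = 1.0 / len(reference)
    for r in reference:
        c[r] += ref_w
    for i in range(ped.n - 1, -1, -1):
        if c[i] == 0.0 or i in blocked:
            continue
        if ped.sire[i] != UNKNOWN:
            c[ped.sire[i]] += 0.5 * c[i]
        if ped.dam[i] != UNKNOWN:
            c[ped.dam[i]] += 0.5 * c[i]
    return c


def _explained_fraction(ped: PedigreeTable, selected: set[int]) -> np.ndarray:
    """Fraction of each individual's genome already explained by ``selected``.

    Downward sweep with selected ancestors absorbing: e = 1 inside the set,
    founders contribute 0, everyone else averages their parents (an unknown
    parent side contributes 0).
    """
    e = np.zeros(ped.n)
    for i in range(ped.n):
        if i in selected:
            e[i] = 1.0
            continue
        val = 0.0
        if ped.sire[i] != UNKNOWN:
            val += 0.5 * e[ped.sire[i]]
        if ped.dam[i] != UNKNOWN:
            val += 0.5 * e[ped.dam[i]]
        e[i] = val
    return e


@dataclass
class FounderStats:
    n_founders: int
    f_e: float
    f_a: float
    founder_contributions: dict[str, float]
    ancestor_contributions: dict[str, float]


def founder_stats(
    ped: PedigreeTable, reference, tol: float = 1e-12
) -> FounderStats:
    """Effective numbers of founders and ancestors for a reference population.

    Founder contributions q_k: each individual transmits half of each
    parent's expected contribution; an individual with an unknown parent
    contributes the corresponding half of its own genome as new (founder)
    material. f_e = 1/sum q_k^2. Ancestors are selected greedily by largest
    marginal contribution (contribution in the pedigree with the selected
    ancestors' parent links cut, scaled by the unexplained fraction of the
    candidate's genome); f_a = 1/sum p_k^2.
    """
    ref_idx = np.array(
        [ped.index[r] if not isinstance(r, (int, np.integer)) else int(r) for r in reference]
    )
    if ref_idx.size == 0:
        raise PedigreeError("reference population is empty")

    raw = _expected_contributions(ped, ref_idx)
    # founder-side contributions: accumulate weight arriving at unknown-parent slots
    q = np.zeros(ped.n)
    c = np.zeros(ped.n)
    for r in ref_idx:
        c[r] += 1.0 / ref_idx.size
    for i in range(ped.n - 1, -1, -1):
        if c[i] == 0.0:
            continue
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN:
            c[s] += 0.5 * c[i]
        else:
            q[i] += 0.5 * c[i]
        if d != UNKNOWN:
            c[d] += 0.5 * c[i]
        else:
            q[i] += 0.5 * c[i]
    f_e = 1.0 / float(np.sum(q**2))

    complete_founders = set(ped.founders().tolist())
    in_or_ancestor = set(ref_idx.tolist())
    for r in ref_idx:
        in_or_ancestor |= ped.ancestors_of(int(r))
    n_founders = len(complete_founders & in_or_ancestor & set(np.flatnonzero(q > tol).tolist()))

    # Boichard greedy ancestor selection; candidates are proper ancestors of
    # at least one reference member (a reference animal qualifies only when
    # it is itself an ancestor of another)
    candidate = np.zeros(ped.n, dtype=bool)
    for r in ref_idx:
        candidate[list(ped.ancestors_of(int(r)))] = True
    selected: list[int] = []
    p_vals: list[float] = []
    selected_set: set[int] = set()
    while True:
        c_cut = _expected_contributions(ped, ref_idx, blocked=selected_set)
        e = _explained_fraction(ped, selected_set)
        marginal = c_cut * (1.0 - e)
        marginal[~candidate] = 0.0
        marginal[list(selected_set)] = 0.0
        k = int(np.argmax(marginal))
        if marginal[k] <= tol:
            break
        selected.append(k)
        p_vals.append(float(marginal[k]))
        selected_set.add(k)
    f_a = 1.0 / float(np.sum(np.array(p_vals) ** 2))
    return FounderStats(
        n_founders=n_founders,
        f_e=f_e,
        f_a=f_a,
        founder_contributions={ped.ids[i]: float(q[i]) for i in np.flatnonzero(q > tol)},
        ancestor_contributions={ped.ids[i]: p for i, p in zip(selected, p_vals)},
    )


# ---------------------------------------------------------------------------
# Assembled metrics
# ---------------------------------------------------------------------------

@dataclass
class PedigreeMetrics:
    n_total: int
    n_inbred: int
    f_mean: float          # fractions, not percents
    f_mean_inbred: float
    ar_mean: float
    delta_f: float
    ne_realized: float
    n_founders: int
    f_e: float
    f_a: float
    gen_max_mean: float
    gen_complete_mean: float
    gen_equiv_mean: float

    def summary(self) -> pd.DataFrame:
        """Human-readable summary (percentages where breeders expect them)."""
        rows = [
            ("Number of analyzed animals", self.n_total),
            ("Number of inbreds", self.n_inbred),
            ("Average inbreeding coefficient", f"{100 * self.f_mean:.2f}%"),
            ("Average inbreeding coefficient in inbreds", f"{100 * self.f_mean_inbred:.2f}%"),
            ("Average relatedness", f"{100 * self.ar_mean:.2f}%"),
            ("Inbreeding rate per generation, dF", f"{100 * self.delta_f:.2f}%"),
            ("Effective population size", f"{self.ne_realized:.2f}"),
            ("Number of founder animals", self.n_founders),
            ("Effective number of founders", f"{self.f_e:.0f}"),
            ("Effective number of ancestors", f"{self.f_a:.0f}"),
            ("Number of maximum generations, mean", f"{self.gen_max_mean:.2f}"),
            ("Number of complete generations, mean", f"{self.gen_complete_mean:.2f}"),
            ("Number of equivalent generations, mean", f"{self.gen_equiv_mean:.2f}"),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value"])


def pedigree_metrics(ped: PedigreeTable, reference=None) -> PedigreeMetrics:
    """Assemble the full genealogical report for a reference population.

    Reference defaults to the offspringless individuals (typically the
    genotyped probands).
    """
    if reference is None:
        reference = ped.offspringless()
    F = inbreeding(ped)
    AR = average_relatedness(ped)
    comp = completeness(ped)
    inbred = F > 1e-12
    delta_f, ne = delta_f_and_ne(F, comp["gen_equiv"].to_numpy())
    fs = founder_stats(ped, reference)
    return PedigreeMetrics(
        n_total=ped.n,
        n_inbred=int(inbred.sum()),
        f_mean=float(F.mean()),
        f_mean_inbred=float(F[inbred].mean()) if inbred.any() else 0.0,
        ar_mean=float(AR.mean()),
        delta_f=delta_f,
        ne_realized=ne,
        n_founders=fs.n_founders,
        f_e=fs.f_e,
        f_a=fs.f_a,
        gen_max_mean=float(comp["gen_max"].mean()),
        gen_complete_mean=float(comp["gen_complete"].mean()),
        gen_equiv_mean=float(comp["gen_equiv"].mean()),
    )


def per_individual_table(ped: PedigreeTable) -> pd.DataFrame:
    """Per-individual F, AR, completeness and dF_i (TSV-ready)."""
    F = inbreeding(ped)
    AR = average_relatedness(ped)
    comp = completeness(ped)
    t = comp["gen_equiv"].to_numpy()
    with np.errstate(invalid="ignore"):
        df_i = np.where(t > 1, 1 - (1 - F) ** (1.0 / np.where(t > 1, t - 1, 1)), np.nan)
    out = comp.copy()
    out.insert(1, "f", F)
    out.insert(2, "ar", AR)
    out["delta_f_i"] = df_i
    return out
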