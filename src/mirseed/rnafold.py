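"""Hairpin-oriented minimum-free-energy RNA secondary-structure folding.

The folder finds the minimum-energy *nested* structure (no pseudoknots) by
dynamic programming under a simplified stacking-energy model:

* allowed pairs: AU, GC and the GU wobble;
* adjacent pairs ``(i, j)``/``(i+1, j-1)`` contribute a stacking energy from
  a packaged table (:data:`DEFAULT_MODEL`);
* every hairpin loop costs a constant closure penalty;
* unpaired bases, bulges, internal loops and multiloop junctions are free;
* minimum hairpin loop of 3 unpaired nucleotides (``j - i >= 4``).

The empty structure has energy zero, so the reported MFE is never positive.
Energies are handled internally in integer tenths of kcal/mol to keep the
DP free of float ties.

Absolute MFE values are model-specific; thresholds such as the −18 kcal/mol
precursor cutoff used by novel-miRNA discovery are calibrated to this
default model and configurable.

Ties on energy are broken toward the structure with the most pairs, then by
a fixed traceback order, so folding is fully deterministic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

from .io_formats import normalize_seq

INF = (10**9, 0)
#: DNA-internal representation of the six admissible pairs, RNA-lettered in
#: the packaged table.
_PAIR_NAMES = {"AT": "AU", "TA": "UA", "GC": "GC", "CG": "CG", "GT": "GU", "TG": "UG"}


class FoldError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyModel:
    """Stacking energies (deci-kcal/mol ints) plus loop parameters."""

    stacks: dict[tuple[str, str], int]
    hairpin_penalty: int = 30  # +3.0 kcal/mol per hairpin loop
    min_loop: int = 3

    def pair_name(self, a: str, b: str) -> str | None:
        return _PAIR_NAMES.get(a + b)

    def pairable(self, a: str, b: str) -> bool:
        return a + b in _PAIR_NAMES

    def stack(self, outer: str, inner: str) -> int:
        return self.stacks[(outer, inner)]


@lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    """Load the packaged stacking table."""
    text = (
        importlib.resources.files("mirseed.data")
        .joinpath("stack_energies.tsv")
        .read_text()
    )
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")[1:]
    stacks: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        outer = parts[0]
        for inner, val in zip(header, parts[1:]):
            stacks[(outer, inner)] = round(float(val) * 10)
    return EnergyModel(stacks=stacks)


@dataclass
class HairpinStructure:
    """A folded sequence: pair list, MFE and derived hairpin geometry."""

    seq: str
    pairs: list[tuple[int, int]]
    mfe_kcal_mol: float
    dotbracket: str

    @property
    def partner(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class HairpinMetrics:
    """Geometry of a mature placed on a folded precursor.

    ``overhang_mature3`` is the number of unpaired bases on the mature's 3'
    side relative to its duplex (2 for a canonical Dicer product);
    ``overhang_star3`` measures the star-side 3' extension and is only
    meaningful when ``seq`` is the precursor proper (no extra 3' flank).
    """

    arm: str  # "5p", "3p" or "spanning"
    overhang_mature3: int | None
    overhang_star3: int | None
    max_bulge: int
    loop_span: tuple[int, int] | None
    star_range: tuple[int, int] | None = None


def _pair_energy_tables(seq: str, model: EnergyModel):
    n = len(seq)
    pairable = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + model.min_loop + 1, n):
            pairable[i][j] = model.pairable(seq[i], seq[j])
    return pairable


def fold(seq: str, model: EnergyModel | None = None) -> HairpinStructure:
    """Fold ``seq`` to its minimum-energy nested structure.

    Raises :class:`FoldError` on invalid characters or out-of-range length
    (5–250 nt supported).
    """
    model = model or default_model()
    try:
        s = normalize_seq(seq)
    except ValueError as exc:
        raise FoldError(str(exc)) from exc
    n = len(s)
    if not (5 <= n <= 250):
        raise FoldError(f"sequence length {n} outside supported range 5-250")

    pairable = _pair_energy_tables(s, model)
    stack = model.stack
    pname = model.pair_name
    ph = model.hairpin_penalty

    # value = (energy_deci, -n_pairs); lexicographic min
    W = [[(0, 0)] * n for _ in range(n)]
    W2 = [[INF] * n for _ in range(n)]
    V = [[INF] * n for _ in range(n)]

    def getW(i: int, j: int):
        return (0, 0) if i > j else W[i][j]

    span_min = model.min_loop + 1
    for length in range(span_min + 1, n + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            # V: best energy with (i, j) paired
            if pairable[i][j]:
                best = (ph, -1)  # hairpin loop
                if j - i >= span_min + 2 and pairable[i + 1][j - 1]:
                    v_in = V[i + 1][j - 1]
                    if v_in is not INF:
                        e = stack(pname(s[i], s[j]), pname(s[i + 1], s[j - 1]))
                        cand = (v_in[0] + e, v_in[1] - 1)
                        if cand < best:
                            best = cand
                w2_in = W2[i + 1][j - 1] if i + 1 <= j - 1 else INF
                if w2_in is not INF:
                    cand = (w2_in[0], w2_in[1] - 1)
                    if cand < best:
                        best = cand
                V[i][j] = best
            # Wpair: i paired with some k
            wp = INF
            for k in range(i + span_min, j + 1):
                vik = V[i][k]
                if vik is INF:
                    continue
                rest = getW(k + 1, j)
                cand = (vik[0] + rest[0], vik[1] + rest[1])
                if cand < wp:
                    wp = cand
            w_up = W[i + 1][j]
            W[i][j] = min(w_up, wp)
            w2_up = W2[i + 1][j]
            W2[i][j] = min(w2_up, wp)

    # traceback (fixed branch order => deterministic structure)
    pairs: list[tuple[int, int]] = []

    def add(a, b):
        return (a[0] + b[0], a[1] + b[1])

    def tb_W(i: int, j: int, target) -> None:
        while i <= j:
            if target == (0, 0) or j - i < span_min:
                return
            # prefer the pairing branch
            done = False
            for k in range(i + span_min, j + 1):
                vik = V[i][k]
                if vik is INF:
                    continue
                rest = getW(k + 1, j)
                if add(vik, rest) == target:
                    tb_V(i, k, vik)
                    i, target = k + 1, rest
                    done = True
                    break
            if done:
                continue
            # i unpaired
            target = W[i + 1][j] if i + 1 <= j else (0, 0)
            i += 1

    def tb_W2(i: int, j: int, target) -> None:
        while i <= j:
            for k in range(i + span_min, j + 1):
                vik = V[i][k]
                if vik is INF:
                    continue
                rest = getW(k + 1, j)
                if add(vik, rest) == target:
                    tb_V(i, k, vik)
                    tb_W(k + 1, j, rest)
                    return
            i += 1
            target = W2[i][j] if i <= j else INF

    def tb_V(i: int, j: int, target) -> None:
        pairs.append((i, j))
        if target == (ph, -1):
            # may coincide with a deeper branch; hairpin (no interior pairs)
            # is the preferred reading on exact ties
            interior_ok = True
        else:
            interior_ok = False
        if not interior_ok:
            if j - i >= span_min + 2 and pairable[i + 1][j - 1] and V[i + 1][j - 1] is not INF:
                e = stack(pname(s[i], s[j]), pname(s[i + 1], s[j - 1]))
                v_in = V[i + 1][j - 1]
                if (v_in[0] + e, v_in[1] - 1) == target:
                    tb_V(i + 1, j - 1, v_in)
                    return
            w2_in = W2[i + 1][j - 1]
            if w2_in is not INF and (w2_in[0], w2_in[1] - 1) == target:
                tb_W2(i + 1, j - 1, w2_in)
                return

    total = W[0][n - 1]
    if total < (0, 0):
        tb_W(0, n - 1, total)
    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return HairpinStructure(
        seq=s,
        pairs=pairs,
        mfe_kcal_mol=total[0] / 10.0,
        dotbracket="".join(db),
    )


def structure_energy(
    seq: str, pairs: list[tuple[int, int]], model: EnergyModel | None = None
) -> float:
    """Energy (kcal/mol) of an explicit nested structure; the model definition.

    Used both by the folder's callers and by the brute-force enumeration
    oracle in the test-suite to score candidate structures.
    """
    model = model or default_model()
    s = normalize_seq(seq)
    partner = {}
    for i, j in pairs:
        if j - i < model.min_loop + 1:
            raise FoldError(f"pair ({i},{j}) violates min loop {model.min_loop}")
        if not model.pairable(s[i], s[j]):
            raise FoldError(f"pair ({i},{j}) = {s[i]}{s[j]} not admissible")
        if i in partner or j in partner:
            raise FoldError("index in more than one pair")
        partner[i] = j
        partner[j] = i
    ordered = sorted(pairs)
    for a, b in ordered:
        for c, d in ordered:
            if a < c < b < d:
                raise FoldError(f"crossing pairs ({a},{b}) and ({c},{d})")
    e = 0
    pairset = set(ordered)
    for i, j in ordered:
        if (i + 1, j - 1) in pairset:
            e += model.stack(model.pair_name(s[i], s[j]), model.pair_name(s[i + 1], s[j - 1]))
        if not any(k in partner and i < k < j for k in range(i + 1, j)):
            e += model.hairpin_penalty
    return e / 10.0


def hairpin_metrics(h: HairpinStructure, mature_range: tuple[int, int]) -> HairpinMetrics:
    """Place a mature on a folded precursor and measure duplex geometry.

    Arm assignment tolerates the canonical 2-nt loop-side overhang: a mature
    is on an arm when all of its paired partners lie on one side and at most
    2 of its 3'-terminal bases are unpaired beyond the duplex; otherwise it
    is "spanning" (e.g. a mature straddling the apex loop).
    """
    start, end = mature_range
    n = len(h.seq)
    if not (0 <= start < end <= n):
        raise ValueError(f"mature_range {mature_range} outside sequence of length {n}")
    partner = h.partner
    mpairs = [(i, partner[i]) for i in range(start, end) if i in partner]
    if not mpairs:
        return HairpinMetrics("spanning", None, None, 0, None)
    ups = [p for i, p in mpairs if p > i]
    downs = [p for i, p in mpairs if p < i]
    if ups and downs:
        return HairpinMetrics("spanning", None, None, _max_bulge(mpairs), None)
    p_lo = min(i for i, _ in mpairs)
    p_hi = max(i for i, _ in mpairs)
    overhang_m3 = (end - 1) - p_hi
    if ups:  # partners downstream: mature on the 5' arm
        arm = "5p"
        inner_partner = partner[p_hi]  # star base facing the loop
        outer_partner = partner[p_lo]  # star base facing the precursor 3' end
        loop_span = (p_hi + 1, inner_partner)
        # canonical geometry: star 3' end = precursor 3' end (valid only when
        # seq is the precursor proper, not a flanked window)
        overhang_s3 = (n - 1) - outer_partner
    else:  # mature on the 3' arm; star is the 5' arm
        arm = "3p"
        inner_partner = partner[p_lo]
        loop_span = (inner_partner + 1, p_lo)
        outer_partner = partner[p_hi]
        # the star's 3' cut lies inside the loop region and cannot be read
        # off the hairpin fold alone
        overhang_s3 = None
    star_lo = min(partner[p_lo], partner[p_hi])
    star_hi = max(partner[p_lo], partner[p_hi])
    if overhang_m3 > 2:
        return HairpinMetrics("spanning", overhang_m3, None, _max_bulge(mpairs), None)
    return HairpinMetrics(
        arm=arm,
        overhang_mature3=overhang_m3,
        overhang_star3=overhang_s3,
        max_bulge=_max_bulge(mpairs),
        loop_span=loop_span,
        star_range=(star_lo, star_hi + 1),
    )


def _max_bulge(mpairs: list[tuple[int, int]]) -> int:
    """Largest internal loop/bulge (total unpaired nt) within the mature duplex."""
    ordered = sorted(mpairs)
    worst = 0
    for (i1, j1), (i2, j2) in zip(ordered, ordered[1:]):
        gap = (i2 - i1 - 1) + abs(j1 - j2) - 1
        worst = max(worst, gap)
    return worst
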