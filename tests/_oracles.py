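"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools
import re

import numpy as np

from plastomarker.ssr import DEFAULT_THRESHOLDS, canonical_motif, _minimal_period

_RC = str.maketrans("ACGTN", "TGCAN")


def regex_ssr_oracle(text: str, thresholds=None):
    """Enumerate maximal perfect tandem runs with a regex lookahead at every
    position, keep left-maximal runs, truncate to whole units, apply the
    smallest-period rule and thresholds. Independent of the scanner."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    found = set()
    n = len(text)
    for k in range(1, 7):
        runs = set()
        for m in re.finditer(rf"(?=(([ACGT]{{{k}}})\2+))", text):
            s, e = m.start(1), m.end(1)
            # regex matches whole units only; extend to the full raw tandem
            # span (possibly ending mid-unit), then dedupe phase-shifted hits
            while s > 0 and text[s - 1] in "ACGT" and text[s - 1] == text[s - 1 + k]:
                s -= 1
            while e < n and text[e] in "ACGT" and text[e] == text[e - k]:
                e += 1
            runs.add((s, e))
        for s, e in runs:
            if _minimal_period(text[s : s + k]) != k:
                continue
            reps = (e - s) // k
            if reps >= thresholds[k]:
                found.add((s, s + k * reps, canonical_motif(text[s : s + k]), k, reps))
    return sorted(found)


def ir_pair_oracle(text: str, min_len: int):
    """All-diagonal scan for the longest exact reverse-complement pair of
    disjoint intervals in a linear sequence. Returns
    ((a0, a1), (b0, b1), length) or None, with the same tie-break as the
    detector (smallest first-copy start, then smallest second-copy start)."""
    n = len(text)
    b = np.frombuffer(text.encode(), dtype=np.uint8)
    rb = np.frombuffer(text.translate(_RC)[::-1].encode(), dtype=np.uint8)
    best = None
    for d in range(-(n - 1), n):
        lo, hi = max(0, -d), min(n, n - d)
        if hi - lo < min_len:
            continue
        eq = b[lo:hi] == rb[lo + d : hi + d]
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for s0, e0 in zip(idx[::2], idx[1::2]):
            s, e = int(s0) + lo, int(e0) + lo
            # copy1 = [n-e-d, n-s-d); clamp at the midpoint if self-overlapping
            if n - e - d < e:
                e = min(e, (n - d) // 2)
            if e - s < min_len:
                continue
            c1 = (n - e - d, n - s - d)
            c2 = (s, e)
            if c1[0] > c2[0]:
                c1, c2 = c2, c1
            key = (e - s, -c1[0], -c2[0])
            if best is None or key > best[0]:
                best = (key, c1, c2, e - s)
    if best is None:
        return None
    return best[1], best[2], best[3]


def hamming_steps_oracle(rows: list[str]):
    """Naive double loop: pairwise-delete Hamming counts over gap/N."""
    n = len(rows)
    out = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            c = 0
            for a, b in zip(rows[i], rows[j]):
                if a in "-N" or b in "-N":
                    continue
                if a != b:
                    c += 1
            out[i][j] = out[j][i] = c
    return out


def minimal_subsets_oracle(profiles: dict[str, dict[str, str]], markers, required_pairs):
    """Brute-force enumeration over all subsets in increasing size."""
    for size in range(1, len(markers) + 1):
        hits = []
        for sub in itertools.combinations(markers, size):
            if all(
                any(profiles[a][m] != profiles[b][m] for m in sub)
                for a, b in required_pairs
            ):
                hits.append(tuple(sub))
        if hits:
            return size, hits
    return None, []


def plant_ssrs(rng, length: int, n_loci: int):
    """Random sequence with planted tandem runs at random positions (the
    background is NOT scrubbed, so incidental runs may also occur; the
    oracle comparison is on whatever the sequence contains)."""
    units = ["A", "T", "AT", "AG", "AAT", "ACT", "AATC", "AACGT", "AACGTC"]
    s = list("".join(rng.choice(list("ACGT"), length)))
    for _ in range(n_loci):
        u = units[int(rng.integers(len(units)))]
        reps = int(rng.integers(DEFAULT_THRESHOLDS[len(u)], DEFAULT_THRESHOLDS[len(u)] + 6))
        run = u * reps
        pos = int(rng.integers(0, length - len(run)))
        s[pos : pos + len(run)] = list(run)
    return "".join(s)
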