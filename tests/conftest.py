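"""Shared fixtures and the independent brute-force scanning oracle."""

from __future__ import annotations

import pytest

from utrcode import CodeConfig, default_patterns, bundled_fixtures

# --- independent oracle -----------------------------------------------------
# A naive re-implementation of motif scanning used to cross-check the
# package's scanner: its own IUPAC table, window enumeration by nested
# loops, and its own interval union.  It must stay independent of
# utrcode.scan / utrcode.motifs internals.

_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_scan(sequence: str, patterns) -> set[tuple[str, int, int]]:
    """All merged same-class match intervals, by exhaustive enumeration."""
    hits: dict[str, list[tuple[int, int]]] = {}
    for pat in patterns:
        p = pat.pattern
        for start in range(len(sequence) - len(p) + 1):
            if all(
                sequence[start + i] in _ORACLE_IUPAC[p[i]] for i in range(len(p))
            ):
                hits.setdefault(pat.element_class, []).append((start, start + len(p)))
    out: set[tuple[str, int, int]] = set()
    for cls, ivals in hits.items():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s < cur_e:
                cur_e = max(cur_e, e)
            else:
                out.add((cls, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.add((cls, cur_s, cur_e))
    return out


# --- shared fixtures --------------------------------------------------------


@pytest.fixture(scope="session")
def fixtures():
    return bundled_fixtures()


@pytest.fixture(scope="session")
def patterns():
    return default_patterns()


@pytest.fixture(scope="session")
def cfg():
    return CodeConfig()
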