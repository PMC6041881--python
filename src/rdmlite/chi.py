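"""CHI (Community Health Index) check-digit validation and free-text scanning.

A CHI number is a 10-digit Scottish patient identifier whose first six
digits are the date of birth (DDMMYY) and whose tenth digit is a modulus-11
check digit over the first nine, with weights 10, 9, ..., 2:

    check = 11 - (sum(w_i * d_i) mod 11),  with 11 -> 0

A remainder yielding check value 10 has no valid check digit, so no valid
CHI exists for that prefix.  The scanner slides a 10-digit window over
every maximal digit run of length >= 10 in every cell, reporting windows
that pass the check — the conservative superset of delimiter conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime

_WEIGHTS = (10, 9, 8, 7, 6, 5, 4, 3, 2)
_DIGIT_RUN = re.compile(r"\d{10,}")


def chi_check_digit(first9: str) -> int | None:
    """Modulus-11 check digit for a 9-digit prefix, or None if impossible."""
    if len(first9) != 9 or not first9.isdigit():
        raise ValueError("expected exactly 9 decimal digits")
    total = sum(w * int(d) for w, d in zip(_WEIGHTS, first9))
    check = (11 - total % 11) % 11
    return None if check == 10 else check


def chi_checksum_valid(digits: str) -> bool:
    """True iff a 10-digit string passes the CHI modulus-11 check."""
    if len(digits) != 10 or not digits.isdigit():
        raise ValueError("expected exactly 10 decimal digits")
    check = chi_check_digit(digits[:9])
    return check is not None and check == int(digits[9])


def chi_date_plausible(digits: str) -> bool:
    """True iff the first six digits parse as a DDMMYY date (strict mode)."""
    try:
        datetime.strptime(digits[:6], "%d%m%y")
        return True
    except ValueError:
        return False


def make_chi(first9: str) -> str | None:
    """Append the check digit to a 9-digit prefix; None if no valid digit."""
    check = chi_check_digit(first9)
    return None if check is None else first9 + str(check)


@dataclass(frozen=True)
class ChiFinding:
    """One checksum-valid 10-digit window found in a cell."""

    dataset_id: str
    column: str
    row_ordinal: int
    matched: str

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "column": self.column,
            "row_ordinal": self.row_ordinal,
            "matched": self.matched,
        }


def scan_text(text: str, *, strict_date: bool = False) -> list[str]:
    """All checksum-valid 10-digit windows within digit runs of a string."""
    found = []
    for run in _DIGIT_RUN.findall(text):
        for start in range(len(run) - 9):
            window = run[start : start + 10]
            if chi_checksum_valid(window) and (not strict_date or chi_date_plausible(window)):
                found.append(window)
    return found


def scan_for_chi(table, dataset_id: str, *, strict_date: bool = False) -> list[ChiFinding]:
    """Scan every cell of a DataFrame for embedded CHI-like numbers.

    Any finding means identifiable data is about to leave the node; the
    extraction pipeline treats a non-empty result as a veto.
    """
    findings: list[ChiFinding] = []
    for ordinal, (_, row) in enumerate(table.iterrows()):
        for column in table.columns:
            value = row[column]
            if value is None or (isinstance(value, float) and value != value):
                continue
            for matched in scan_text(str(value), strict_date=strict_date):
                findings.append(
                    ChiFinding(dataset_id=dataset_id, column=column, row_ordinal=ordinal, matched=matched)
                )
    return findings
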