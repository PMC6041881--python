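"""Independent oracles used by the test suite and the acceptance script.

Each function here re-derives an expected result by a route separate from
the library implementation: a from-scratch MD5, a brute-force replay of
raw feeds for as-at reconstruction, and an explicit modulus-11 check.
"""

import math
import struct

# -- pure-Python MD5 (second implementation, independent of hashlib) -------

_S = [7, 12, 17, 22] * 4 + [5, 9, 14, 20] * 4 + [4, 11, 16, 23] * 4 + [6, 10, 15, 21] * 4
_K = [int(abs(math.sin(i + 1)) * 2**32) & 0xFFFFFFFF for i in range(64)]


def md5_hex(data: bytes) -> str:
    a0, b0, c0, d0 = 0x67452301, 0xEFCDAB89, 0x98BADCFE, 0x10325476
    msg = bytearray(data) + b"\x80"
    while len(msg) % 64 != 56:
        msg += b"\x00"
    msg += struct.pack("<Q", (8 * len(data)) & 0xFFFFFFFFFFFFFFFF)
    for offset in range(0, len(msg), 64):
        m = struct.unpack("<16I", bytes(msg[offset : offset + 64]))
        a, b, c, d = a0, b0, c0, d0
        for i in range(64):
            if i < 16:
                f, g = (b & c) | (~b & d), i
            elif i < 32:
                f, g = (d & b) | (~d & c), (5 * i + 1) % 16
            elif i < 48:
                f, g = b ^ c ^ d, (3 * i + 5) % 16
            else:
                f, g = c ^ (b | ~d), (7 * i) % 16
            f = (f + a + _K[i] + m[g]) & 0xFFFFFFFF
            a, d, c = d, c, b
            b = (b + ((f << _S[i] | f >> (32 - _S[i])) & 0xFFFFFFFF)) & 0xFFFFFFFF
        a0, b0, c0, d0 = (a0 + a) & 0xFFFFFFFF, (b0 + b) & 0xFFFFFFFF, (c0 + c) & 0xFFFFFFFF, (d0 + d) & 0xFFFFFFFF
    return struct.pack("<4I", a0, b0, c0, d0).hex()


# -- brute-force as-at replay ----------------------------------------------


def replay_as_at(feeds, t, pk_cols, null_tokens=("", "NULL", "NA")):
    """Replay raw feeds up to time t and return the surviving rows.

    ``feeds`` is a list of (load_time, columns, rows) with rows as lists of
    raw strings.  Within one feed the first occurrence of a primary key
    wins (later in-batch duplicates are dropped); across feeds the latest
    feed wins.  Returns a dict key -> row dict with trimmed values and
    nulls as None.
    """
    state = {}
    for load_time, columns, rows in sorted(feeds, key=lambda f: f[0]):
        if load_time > t:
            continue
        seen = set()
        for raw in rows:
            row = {}
            for col, value in zip(columns, raw):
                value = value.strip()
                row[col] = None if value in null_tokens else value
            key = tuple(row.get(c) for c in pk_cols)
            if any(v is None for v in key) or key in seen:
                continue
            seen.add(key)
            state[key] = row
    return state


# -- explicit modulus-11 check ---------------------------------------------


def mod11_valid(digits: str) -> bool:
    """Positional re-derivation of the CHI check: weight 10-i on digit i."""
    total = 0
    for i in range(9):
        total += int(digits[i]) * (10 - i)
    check = 11 - total % 11
    if check == 11:
        check = 0
    if check == 10:
        return False
    return check == int(digits[9])
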