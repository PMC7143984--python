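"""Independent brute-force reference implementations for the test suite.

Everything here is written with explicit Python loops and the plain
summation formulas, deliberately sharing no code with the package.
"""

import math


def mean(v):
    return sum(v) / len(v)


def pearson(x, y):
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    return (n * sxy - sx * sy) / math.sqrt(
        (n * sxx - sx * sx) * (n * syy - sy * sy)
    )


def ccc(x, y):
    xb, yb = mean(x), mean(y)
    num = 2.0 * sum((a - xb) * (b - yb) for a, b in zip(x, y))
    den = (
        sum((a - xb) ** 2 for a in x)
        + sum((b - yb) ** 2 for b in y)
        + len(x) * (xb - yb) ** 2
    )
    return num / den


def through_origin(y, yt):
    """(k, k', r0_sq, r0_sq_primed) with y observed, yt predicted."""
    s_yyt = sum(a * b for a, b in zip(y, yt))
    k = s_yyt / sum(b * b for b in yt)
    k_prime = s_yyt / sum(a * a for a in y)
    ytb = mean(yt)
    yb = mean(y)
    r0 = 1.0 - sum((b - k_prime * a) ** 2 for a, b in zip(y, yt)) / sum(
        (b - ytb) ** 2 for b in yt
    )
    r0p = 1.0 - sum((a - k * b) ** 2 for a, b in zip(y, yt)) / sum(
        (a - yb) ** 2 for a in y
    )
    return k, k_prime, r0, r0p


def q2_family(y, yhat, mean_tr, var_tr):
    press = sum((a - b) ** 2 for a, b in zip(y, yhat))
    yb = mean(y)
    q2 = 1.0 - press / sum((a - yb) ** 2 for a in y)
    f1 = 1.0 - press / sum((a - mean_tr) ** 2 for a in y)
    f2 = q2
    f3 = 1.0 - (press / len(y)) / var_tr
    return q2, f1, f2, f3


def rm2(y, yt, sqrt_form=True):
    def one(a, b):
        r2 = pearson(a, b) ** 2
        _, _, r0, _ = through_origin(a, b)
        gap = abs(r2 - r0)
        if sqrt_form:
            gap = math.sqrt(gap)
        return r2 * (1.0 - gap)

    fwd, rev = one(y, yt), one(yt, y)
    return (fwd + rev) / 2.0, abs(fwd - rev)


def iic(y, ycalc, r_cal):
    neg = [abs(a - b) for a, b in zip(y, ycalc) if a - b < 0]
    pos = [abs(a - b) for a, b in zip(y, ycalc) if a - b >= 0]
    if not neg or not pos:
        return 0.0
    mn, mp = mean(neg), mean(pos)
    return r_cal * min(mn, mp) / max(mn, mp)


def char_walk_tokenize(smiles):
    """Naive character-by-character SMILES tokenizer (greedy)."""
    out = []
    i = 0
    while i < len(smiles):
        if smiles[i] in "CB" and i + 1 < len(smiles) and (
            smiles[i : i + 2] == "Cl" or smiles[i : i + 2] == "Br"
        ):
            out.append(smiles[i : i + 2])
            i += 2
        elif smiles[i] == "@" and i + 1 < len(smiles) and smiles[i + 1] == "@":
            out.append("@@")
            i += 2
        elif smiles[i] == "%":
            out.append(smiles[i : i + 3])
            i += 3
        else:
            out.append(smiles[i])
            i += 1
    return ["(" if t == ")" else t for t in out]
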