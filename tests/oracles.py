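"""Independent closed-form oracles used by the test suite.

These re-derive, from the published formulas, statistics that the package
obtains through scipy — so implementation and check stay on separate
routes.
"""

import numpy as np


def dagostino_pearson_k2(x):
    """D'Agostino-Pearson omnibus test from first principles.

    Combines D'Agostino's skewness z-score and the Anscombe-Glynn kurtosis
    z-score into K2 = z_s^2 + z_k^2, chi-square with 2 df; the survival
    function of chi-square(2) is exp(-K2/2) in closed form.
    """
    x = np.asarray(x, float)
    n = len(x)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)

    # skewness: D'Agostino (1970)
    b1 = m3 / m2 ** 1.5
    y = b1 * np.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
    beta2 = (
        3.0 * (n ** 2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
        / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0))
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    z_skew = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))

    # kurtosis: Anscombe & Glynn (1983)
    b2 = m4 / m2 ** 2
    e_b2 = 3.0 * (n - 1.0) / (n + 1.0)
    var_b2 = (
        24.0 * n * (n - 2.0) * (n - 3.0)
        / ((n + 1.0) ** 2 * (n + 3.0) * (n + 5.0))
    )
    xx = (b2 - e_b2) / np.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n ** 2 - 5.0 * n + 2.0) / ((n + 7.0) * (n + 9.0))
        * np.sqrt(6.0 * (n + 3.0) * (n + 5.0) / (n * (n - 2.0) * (n - 3.0)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (
        2.0 / sqrt_beta1 + np.sqrt(1.0 + 4.0 / sqrt_beta1 ** 2)
    )
    term = (1.0 - 2.0 / a) / (1.0 + xx * np.sqrt(2.0 / (a - 4.0)))
    z_kurt = ((1.0 - 2.0 / (9.0 * a)) - np.cbrt(term)) / np.sqrt(2.0 / (9.0 * a))

    k2 = z_skew ** 2 + z_kurt ** 2
    return k2, float(np.exp(-k2 / 2.0))


def welch_t(a, b):
    """Welch's unequal-variance t statistic and Welch-Satterthwaite df."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return t, df


def paired_t(pre, post):
    """Paired t statistic on (pre - post) differences."""
    d = np.asarray(pre, float) - np.asarray(post, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, n - 1
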