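"""Informational benchmark: spectral vs QR score-statistic evaluation.

Writes a TSV of per-call timings for a grid of (n cells, q covariates,
t treatment cells).  Usage: python scripts/benchmark_score.py [--out PATH]
"""

from __future__ import annotations

import argparse
import time

import numpy as np
import pandas as pd

from permscreen.nb_glm import fit_null_glm
from permscreen.score import precompute, score_stat, score_stat_qr_oracle


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", default="scratch/score_benchmark.tsv")
    parser.add_argument("--reps", type=int, default=200)
    args = parser.parse_args()

    rng = np.random.default_rng(0)
    rows = []
    for n, q, t in [(2000, 2, 50), (2000, 6, 50), (10_000, 6, 100), (10_000, 10, 400)]:
        Z = np.column_stack([np.ones(n), rng.standard_normal((n, q - 1))])
        mu = np.exp(0.5 + 0.2 * Z[:, 1])
        y = rng.negative_binomial(4.0, 4.0 / (4.0 + mu))
        fit = fit_null_glm(y, Z, family="nb", theta=4.0)
        pc = precompute(fit, Z)
        idxs = [np.sort(rng.choice(n, t, replace=False)) for _ in range(args.reps)]

        t0 = time.perf_counter()
        for idx in idxs:
            score_stat(idx, pc)
        spectral = (time.perf_counter() - t0) / args.reps

        xs = []
        for idx in idxs:
            x = np.zeros(n)
            x[idx] = 1.0
            xs.append(x)
        t0 = time.perf_counter()
        for x in xs:
            score_stat_qr_oracle(x, fit, Z)
        qr = (time.perf_counter() - t0) / args.reps

        rows.append(
            {"n": n, "q": q, "t": t, "spectral_s": spectral, "qr_s": qr,
             "speedup": qr / spectral}
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(args.out, sep="\t", index=False)
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
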