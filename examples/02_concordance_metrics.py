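"""The four TF-to-target concordance metrics on toy expression profiles.

Builds three smoothed 20-bin profiles — a sigmoid "TF", a noise-free copy
delayed by 3 bins, and an unrelated bump — and prints what each metric sees.
Squared correlations live in [0, 1] (sign kept aside), DTW is a distance
(smaller = tighter alignment), MI is in nats, and the rolling variant reports
the best lag.
"""

import numpy as np

import branchtf as bt

t = np.linspace(0, 1, 20)
tf = 1.0 / (1.0 + np.exp(-10 * (t - 0.45)))
lagged_target = np.concatenate([np.full(3, tf[0]), tf[:-3]])
unrelated = np.exp(-0.5 * ((t - 0.3) / 0.12) ** 2)

for name, y in [("lagged target", lagged_target), ("unrelated gene", unrelated)]:
    r2, sign = bt.pearson_sq(tf, y)
    s2, _ = bt.spearman_sq(tf, y)
    d = bt.dtw_distance(tf, y)
    mi = bt.mutual_information(tf, y)
    score, _, lag = bt.rolling_best("pearson", tf, y, max_lag=5)
    print(f"TF vs {name}:")
    print(f"  Pearson^2 = {r2:.3f} (sign {sign:+d})   Spearman^2 = {s2:.3f}")
    print(f"  DTW distance = {d:.4f}   MI = {mi:.3f} nats")
    print(f"  rolling Pearson^2 = {score:.3f} at lag {lag} bins")
    print()

print("The delayed copy is imperfect at lag 0 but perfect once the rolling")
print("scan shifts the target back by the planted 3 bins; the unrelated bump")
print("stays weak at every lag and keeps a large DTW distance.")
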