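"""Stratified 70/20/10 split with largest-remainder apportionment.

For per-class totals (350, 300, 250, 439) the integer counts must come
out exactly as printed below — in particular 439 -> 307/88/44, which
naive flooring (307/87/43) cannot produce.
"""

import numpy as np

from thermoclass import stratified_split

totals = {"DCIS": 350, "ILC": 300, "Angiosarcoma": 250, "PhyllodesTumor": 439}
labels = np.repeat(np.arange(4), list(totals.values()))
split = stratified_split(labels, (0.70, 0.20, 0.10), seed=0)

print(f"{'class':16s} {'total':>6s} {'train':>6s} {'test':>6s} {'valid':>6s}")
for idx, (name, total) in enumerate(totals.items()):
    tr, te, va = split.per_class_counts[idx]
    print(f"{name:16s} {total:6d} {tr:6d} {te:6d} {va:6d}")
tr, te, va = split.counts()
print(f"{'all':16s} {len(labels):6d} {tr:6d} {te:6d} {va:6d}")
# counts are seed-independent; the seed only shuffles which record lands where
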