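"""The five variability indices across sampling rates and both downsamplers.

Computes the index battery for one preprocessed synthetic trace over the
1 s - 30 min interval grid and prints SV for both downsampling methods.  SV
weighs frequencies near the sampling rate most strongly, so instantaneous
subsampling keeps (aliased) fast noise while bin averaging suppresses it —
the two curves separate as the interval grows.
"""

import numpy as np

from bpvar import index_battery, preprocess
from bpvar.synthetic import SynthConfig, generate_trace

cfg = SynthConfig(truncation_probs=(1, 0, 0))
trace = generate_trace(cfg, "unfavorable", np.random.default_rng(5), duration_h=24.0)
ct = preprocess(trace)

battery = index_battery(ct)
one_s = battery[battery.interval_s == 1.0].iloc[0]
print("native 1 s indices:")
print(
    f"  mean {one_s['mean']:.1f} mmHg  sd {one_s.sd:.2f}  cv {one_s.cv:.4f}  "
    f"arv {one_s.arv:.2f}  sv {one_s.sv:.2f}  tc {one_s.tc:.3f}  (n={int(one_s.n)})"
)
print("\nSV (mmHg) by sampling interval and method:")
print(f"{'interval':>10} {'instantaneous':>14} {'averaging':>10}")
for interval in sorted(battery.interval_s.unique()):
    sub = battery[battery.interval_s == interval]
    sv = dict(zip(sub.method, sub.sv))
    print(f"{interval:>8.0f} s {sv['instantaneous']:>14.2f} {sv['averaging']:>10.2f}")
print("\nAveraging acts as a low-pass filter: its SV reflects band-limited")
print("variability near the new Nyquist rate instead of aliased fast noise.")
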