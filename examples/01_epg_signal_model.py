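"""CPMG echo trains under imperfect refocusing.

Simulates the multi-echo signal of a T2 = 95 ms tissue at nominal flip
(B1 = 1.0) and with a 15% transmit deficit (B1 = 0.85), and compares both
against the ideal mono-exponential decay.
"""

import numpy as np

from drg_t2map import EchoTrainParams, epg_cpmg

params = EchoTrainParams()  # 10 echoes, 15 ms spacing, TR 4.8 s
te = params.echo_times_ms
t2 = 95.0

ideal = np.exp(-te / t2)
nominal = epg_cpmg(t2, 1000.0, 1.0, params)
deficit = epg_cpmg(t2, 1000.0, 0.85, params)

print(f"{'TE [ms]':>8} {'exp(-TE/T2)':>12} {'EPG b1=1.0':>12} {'EPG b1=0.85':>12}")
for i in range(params.n_echoes):
    print(f"{te[i]:8.0f} {ideal[i]:12.6f} {nominal[i]:12.6f} {deficit[i]:12.6f}")

print(
    "\nAt B1 = 1.0 the EPG train is exactly mono-exponential.  At B1 = 0.85 the"
    "\nfirst echo loses signal while stimulated-echo pathways prop up later"
    "\nechoes — a naive exponential fit of that train overestimates T2, which"
    "\nis why the B1-corrected dictionary fit exists."
)
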