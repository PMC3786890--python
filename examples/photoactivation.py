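"""In silico photoactivation: do tip motors return to the cell body?

Pre-equilibrates a 5000-motor Loose-Bucket-Brigade ensemble in a 30 µm
process, photoactivates (labels) motors in the distal window either once or
repeatedly (10 activations, 4 min apart), and tracks the labelled count in
the proximal soma window over 40 min of imaging. Takes ~2 minutes.
"""

import kinesim as ks
from kinesim import montecarlo as mc

p = ks.PAPER_PARAMS
geom = ks.Geometry1D(30.0)

final = {}
for mode in ("none", "single", "repeated"):
    prot = mc.ActivationProtocol(mode=mode)
    df = mc.photoactivation_experiment(
        prot, ks.LOOSE_BUCKET_BRIGADE, p, geom, 5000, seed=7, dt=0.05
    )
    final[mode] = df["soma_count"].tail(5).mean()
    marks = df["soma_count"].iloc[::8].tolist()
    print(f"{mode:9s} soma-window labelled count every 8 min: {marks}")

print(f"\nfinal (last 5 frames, mean): none={final['none']:.1f}  "
      f"single={final['single']:.1f}  repeated={final['repeated']:.1f}")
print(
    "\nNo activation gives exactly zero; a single tip activation sends only a"
    "\ntrickle of labelled motors back to the base (diffusive return over many"
    "\nλ is rare), while repeated activation keeps relabelling the tip pool and"
    "\naccumulates a clearly larger soma signal at the same total imaging time."
)
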