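"""Generate a synthetic 48-h fecal-fermentation study and look at one arm.

Builds the default procyanidin catabolic network (two hydrolysis routes to
phenylacetic and phenylvaleric metabolites, plus a carbohydrate pool feeding
the SCFAs), simulates 4 donors x 3 matrices x 3 replicates plus a no-matrix
control arm per donor on the 9-point sampling grid, and prints the acetate
series of one fermenter.
"""

import numpy as np

from fermkin import build_default_network, generate_study

network = build_default_network()
print(f"network: {len(network.species)} species, {len(network.edges)} edges")
print(f"end-products (no outgoing edge): {', '.join(network.sinks)}")

study = generate_study(seed=42)
print(f"\ngenerated {len(study)} time courses "
      f"(4 donors x 4 arms incl. control x 3 replicates x 4 analytes)")

arm = next(tc for tc in study
           if tc.key == ("O1", "Mnc", 1, "acetate"))
print(f"\nacetate, donor O1, matrix Mnc, replicate 1 (mM):")
for t, c in zip(arm.times, arm.conc):
    print(f"  t={t:4.0f} h   {c:7.2f}")
print("\nThe series rises from the endogenous baseline toward a plateau by "
      "48 h,\nwith ~5%-of-range measurement noise, as in a real batch "
      "fermenter.")
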