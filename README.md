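# hexalig

Statistical-thermodynamic analysis of ATP binding to the heterogeneous
oligomers of the *E. coli* transcription termination factor Rho.

Rho is a hexameric helicase, but in solution it populates everything from
monomer to hexamer, and each j-mer presents a different mix of binding
sites: j − 1 intact sites enclosed at subunit interfaces plus two partially
formed sites at the open washer's edges. Conventional one-dimensional
binding isotherms average over all of this; native mass spectrometry (nMS)
resolves every (oligomer, bound-ATP) species at once, and mass photometry
(MP) counts the oligomers particle by particle. This package is for
biophysicists who want to analyze — or rehearse the analysis of — such data:
it implements the forward models (spectra, particle histograms), the
measurement reduction (windowed peak extraction into within-oligomer
population matrices), and the inference (maximum-likelihood lattice-model
fitting with bootstrap uncertainty), all exercisable end to end on synthetic
data with known ground truth.

## Model

A j-mer's sites form a 1-D lattice. With free ligand L, the weight of an
occupancy configuration *s* is

    W(s) = Π_i (K_class(i) · L)^{s_i} · ω^{n_adj(s)}

where K_full and K_partial are intrinsic association constants of intact and
edge sites and ω is a nearest-neighbor coupling applied per adjacent
occupied pair (ω < 1: anti-cooperative). The binding polynomial
Z(L) = Σ_k a_k L^k gives the liganded-population distribution
P(k) = a_k L^k / Z. Oligomers interconvert through an assembly ladder
β_j = σ·K_step^{j−1}, linked to binding through shared free-monomer and
free-ligand mass balances, so the concentration of the j-mer with k ATP is
c(j,k) = β_j m^j a_k^{(j)} l^k.

## Worked example

```python
import numpy as np
from hexalig import (
    AssemblyParameters, BindingParameters, SolutionConditions,
    build_topology, default_topologies, occupancy_distribution, speciate,
)

# hexamer washer: 5 intact + 2 edge sites; Kd 10 / 100 uM, omega = 0.5
hexamer = build_topology(6, "open_chain")
binding = BindingParameters.with_shared_partial(1e5, 1e4, 0.5)
print(np.round(occupancy_distribution(hexamer, binding, 10e-6).probs, 3))
# [0.043 0.226 0.387 0.262 0.073 0.008 0.    0.   ]

# full speciation at 10 uM protomer, 10 uM total ATP
assembly = AssemblyParameters.nucleated(2e8, 0.1)
table = speciate(assembly, binding, default_topologies(),
                 SolutionConditions(10e-6, 10e-6))
print(f"free ATP {table.free_ligand*1e6:.2f} uM")   # free ATP 7.06 uM
```

At 10 μM free ATP the hexamer most often carries two ATP, with occupancy
held well below its five intact sites by the negative coupling and the weak
edges. At equimolar total ATP nearly 30% of the nucleotide is protein-bound
(free ATP 7.06 of 10 μM), which is why the fitting machinery resolves free
ligand through the mass balance instead of using the total.

The `analysis/` scripts run the full narrative on synthetic data: simulate
the 0–100 μM titration (`01`), extract population matrices from the spectra
(`02`, worst round-trip error ~0.016 at realistic noise), refit the lattice
model to the hexamer rows (`03`, recovering K_d(full) = 10.1 μM and
ω = 0.46 < 1 from generating values 10 μM / 0.5), and fit the assembly
ladder to an MP dilution series (`04`, apparent K_d 0.100 μM vs. ~0.102 μM
generated). The same pipeline is scriptable via the `hexalig` CLI
(`simulate`, `extract`, `fit`, `mp-fit`, `run`) with a YAML config.

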