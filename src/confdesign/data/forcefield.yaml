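# Self-consistent nonbonded parameter set for the five-term design energy
# function.  These tables are a compact stand-in written for this package:
# the published design-software parameter tables are not publicly available,
# so absolute energies computed with this set are internally consistent but
# not comparable to externally reported design energies.
version: "confdesign-ff-0.1"
lj_scale: 0.9          # applied to per-type r0 before combination
clash_cap: 100.0       # kcal/mol, cap for clashing contacts
cutoff: 8.0            # Å, nonbonded cutoff (no switching function)
hbond:
  d0: 8.0              # kcal/mol well depth
  r0: 2.8              # Å equilibrium donor-acceptor distance
  max_distance: 3.5    # Å, beyond which no H-bond is evaluated
dielectric:
  model: distance_dependent   # epsilon(r) = epsilon * r (r in Å)
  epsilon: 10.0
solvation:
  length: 3.5          # Å, Gaussian occlusion kernel correlation length
elements:
  C: {r0: 3.898, eps: 0.0951, vref: 25.0, solv_coeff: 0.005}
  N: {r0: 3.662, eps: 0.0774, vref: 18.0, solv_coeff: 0.030}
  O: {r0: 3.405, eps: 0.0957, vref: 16.0, solv_coeff: 0.030}
  S: {r0: 4.030, eps: 0.3440, vref: 30.0, solv_coeff: 0.010}
  P: {r0: 4.150, eps: 0.3200, vref: 28.0, solv_coeff: 0.015}
  H: {r0: 3.195, eps: 0.0152, vref: 5.0, solv_coeff: 0.0}
charges:
  # exact backbone atom names first, then side-chain prefix fallback by
  # leading element letter, then 0
  names: {N: -0.47, O: -0.51, OXT: -0.51, C: 0.51, CA: 0.07, CB: 0.0}
  prefixes: {O: -0.45, N: -0.35, S: -0.15, C: 0.0, P: 0.30}
donors: [N, NE, NH1, NH2, ND1, NE2, ND2, NZ, NE1, OG, OG1, OH, SG]
acceptor_elements: [O]
acceptor_names: [ND1, NE2, SD]
ss_propensity:   # kcal/mol, residue type x secondary-structure class
  helix:
    ALA: -0.40
    LEU: -0.25
    MET: -0.20
    GLU: -0.25
    GLN: -0.15
    LYS: -0.15
    ARG: -0.10
    PHE: 0.05
    TRP: 0.05
    HIS: 0.10
    ILE: 0.10
    TYR: 0.10
    SER: 0.15
    CYS: 0.20
    VAL: 0.20
    THR: 0.25
    ASN: 0.30
    ASP: 0.30
    GLY: 1.00
    PRO: 2.00
  strand:
    VAL: -0.40
    ILE: -0.40
    TYR: -0.25
    PHE: -0.20
    THR: -0.20
    TRP: -0.15
    CYS: -0.10
    LEU: -0.10
    MET: 0.00
    ARG: 0.05
    HIS: 0.10
    SER: 0.10
    LYS: 0.10
    GLN: 0.15
    ALA: 0.20
    ASN: 0.30
    GLU: 0.30
    ASP: 0.40
    GLY: 0.80
    PRO: 1.50
  other:
    PRO: -0.40
    GLY: -0.30
    ASN: -0.20
    ASP: -0.20
    SER: -0.10
    ALA: 0.10
    LEU: 0.10
    VAL: 0.15
    ILE: 0.15
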