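# Bundled reference component interaction energies (kcal/mol, water phase,
# counterpoise-corrected M05-2X/6-31G(d,p) + COSMO ab initio values) for
# idealized backbone-stripped nucleobase assemblies.
# class: pair = Watson-Crick/mismatch pairing energy (dE_pair)
#        hoogsteen = Hoogsteen pairing energy within a triad (dE_Hoogsteen)
#        tetrad_ionic = G-tetrad formation energy (dE_G-tetrad); the per-bond
#                       column is the per-ionic-bond dE_ionic = total/4
#        stack = two-layer stacking energy (dE_stack)
#        sum_ionic = total ionic-bond energy of a two-layer quadruplex
#                    (sum dE_ionic); per-bond column as printed in the source
# per_bond_kcal_mol is transcribed as printed (round-half-away-from-zero at
# the printed precision), not recomputed.
# flag ion_bond_count_ambiguous: the printed per-bond value implies division
# by 8 ionic bonds, but the in-plane Li+ quadruplex is described with only
# four Li+...O bonds; both readings are preserved, neither is resolved here.
structure_id,class,phase,total_kcal_mol,n_bonds,per_bond_kcal_mol,source_location,flag
G-C,pair,water,-11.45,3,-3.82,ref:pair,
A-T,pair,water,-6.80,2,-3.40,ref:pair,
G-T,pair,water,-6.77,2,-3.38,ref:pair,
G-G,pair,water,-6.75,2,-3.37,ref:pair,
C-T,pair,water,-6.58,2,-3.29,ref:pair,
T-T,pair,water,-6.43,2,-3.21,ref:pair,
A-G,pair,water,-6.41,2,-3.20,ref:pair,
A-C,pair,water,-3.39,2,-1.70,ref:pair,
A-A,pair,water,-3.25,2,-1.62,ref:pair,
C-C,pair,water,-3.16,1,,ref:pair,
C+.G,hoogsteen,water,-11.04,2,-5.52,ref:triad,
G.G,hoogsteen,water,-7.81,2,-3.91,ref:triad,
T.A,hoogsteen,water,-6.50,2,-3.25,ref:triad,
A.A,hoogsteen,water,-1.69,2,-0.84,ref:triad,
rC+.G,hoogsteen,water,-11.08,2,-5.54,ref:triad,
rG.G,hoogsteen,water,-7.64,2,-3.82,ref:triad,
rT.A,hoogsteen,water,-4.90,2,-2.45,ref:triad,
rA.A,hoogsteen,water,-3.83,2,-1.92,ref:triad,
G4_Li,tetrad_ionic,water,-31.28,4,-7.82,ref:tetrad,
G4_Na,tetrad_ionic,water,-27.68,4,-6.92,ref:tetrad,
G4_K,tetrad_ionic,water,-20.26,4,-5.07,ref:tetrad,
G-C/C-G,stack,water,-5.46,,,ref:duplex,
A-T/A-T,stack,water,-5.22,,,ref:duplex,
G-C/A-T,stack,water,-5.21,,,ref:duplex,
A-T/T-A,stack,water,-5.05,,,ref:duplex,
G-C/G-C,stack,water,-4.88,,,ref:duplex,
G-C/T-A,stack,water,-4.04,,,ref:duplex,
A.A-T/A.A-T,stack,water,-11.87,,,ref:triplex,
C+.G-C/T.A-T,stack,water,-8.56,,,ref:triplex,
G.G-C/G.G-C,stack,water,-7.78,,,ref:triplex,
T.A-T/T.A-T,stack,water,-7.37,,,ref:triplex,
C+.G-C/C+.G-C,stack,water,-3.77,,,ref:triplex,
rT.A-T/rT.A-T,stack,water,-13.07,,,ref:triplex,
rA.A-T/rA.A-T,stack,water,-12.19,,,ref:triplex,
rG.G-C/rG.G-C,stack,water,-7.07,,,ref:triplex,
rC+.G-C/rC+.G-C,stack,water,-4.10,,,ref:triplex,
G4/G4,stack,water,-13.16,,,ref:quadruplex,
G4_Na_G4,sum_ionic,water,-39.1,8,-4.9,ref:quadruplex,
G4_K_G4,sum_ionic,water,-37.0,8,-4.6,ref:quadruplex,
G4_Li_G4,sum_ionic,water,-32.8,8,-4.1,ref:quadruplex,ion_bond_count_ambiguous
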