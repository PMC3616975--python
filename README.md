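# tetherdock

Informatics-guided, tether-constrained protein–protein docking for
two-domain systems, built for the JAK-family problem of how a pseudokinase
domain (JH2) packs against and auto-inhibits its tandem tyrosine kinase
domain (JH1) when the two are joined by a short covalent linker.

The toolkit implements the full workflow as composable library stages plus
a thin CLI:

1. **Site nomination** — corrected mutual information (nats) between residue
   torsion distributions (φ/ψ and χ1–χ4) across a conformational ensemble,
   with a frame-permutation significance null; hierarchical clustering of
   the coupling matrix groups highly coupled residues into candidate
   interface/allosteric sites.
2. **Pose seeding and sampling** — the two domains are joined face-to-face
   through their nominated surface patches, then rigid-body poses are drawn
   with the classic local-docking Gaussian move set: translations of
   N(0, 3 Å) along the line connecting the domain centers and N(0, 8 Å) in
   each perpendicular direction, a N(0, 8°) rotation about the center axis,
   and a N(0, 8°) tilt of that axis. 10,000 poses per configuration by
   default.
3. **Tether filter** — poses whose linked termini (Cα–Cα) sit farther apart
   than the linker can span (60 Å cutoff, inclusive) are discarded.
4. **Clustering** — survivors are compared by *tethered RMSD* (mobile-domain
   Cα RMSD after Kabsch superposition of the static domain) and clustered
   NMRCLUST-style: average linkage cut at the step minimizing normalized
   average spread + normalized cluster count; medoids represent the top 5
   clusters by size.
5. **Ranking** — each representative complex is scored with the interface
   metric panel: buried surface area
   `BSA = SASA(A) + SASA(B) − SASA(AB)` (Shrake–Rupley, 1.4 Å probe),
   hydrophobic contacts (side-chain heavy atoms within 5 Å), ionic contacts
   and salt bridges (charged groups within 6 Å), π-stacking (ring centroids
   4.5–7.0 Å), and a simplified interaction energy
   `E_bind = E_complex − E_A − E_B = E_ele + E_vdw`
   (cross-domain Coulomb + Lennard-Jones; a transparent ranking proxy, not
   a force field). Ensemble analytics (superposition RMSF, segment RMSD and
   distance monitors) assemble the per-model ranking table.

A synthetic-fixture module generates ideal-geometry helical domains,
planted-feature complexes, jittered and coupled-rotamer ensembles, and
planted pose families, so everything runs and is tested without downloads.

## Worked example

```python
import numpy as np
from tetherdock.fixtures import make_helix_domain, make_rotamer_ensemble
from tetherdock.pipeline import PipelineConfig, run_couple, run_dock, run_triage
from tetherdock.structure import DomainDefinition
from tetherdock.tether import TetherSpec

cfg = PipelineConfig(n_poses=120, sampling_seed=11,
                     n_permutations=60, n_sphere_points=120)

# 1. nominate sites from a torsion-coupled ensemble
ens, _ = make_rotamer_ensemble(6, [(1, 4, np.array([[.45, .05], [.05, .45]]))],
                               800, seed=6)
matrix, sites = run_couple(ens, cfg, torsion_labels={"chi1"})
print(sites[0].residue_keys)       # {('A', 2, ''), ('A', 5, '')}

# 2-5. dock, filter, cluster, report
static = make_helix_domain("ALKEFYRDILAVLKEA", chain="A")
mobile = make_helix_domain("ILKDFYREILAVLKEA", chain="B", start_residue=101)
seed_pose, poses = run_dock(static, mobile,
                            [("A", 8, ""), ("A", 9, "")],
                            [("B", 108, ""), ("B", 109, "")], cfg)
res = run_triage(poses, static, mobile,
                 TetherSpec(("A", 16, ""), ("B", 101, ""), cutoff=60.0), cfg,
                 DomainDefinition("static", "A", 1, 16),
                 DomainDefinition("mobile", "B", 101, 116))
print(res["tether_report"].n_kept, "of", res["tether_report"].n_input,
      "poses within the 60 Å tether")
print(len(res["representatives"]), "representative poses")
for p, r in zip(res["representatives"], res["reports"]):
    print(p.id, f"BSA={r.bsa:.0f} Å², I/H={r.n_ionic}/{r.n_hydrophobic}")
```

Output:

```
{('A', 2, ''), ('A', 5, '')}
120 of 120 poses within the 60 Å tether
5 representative poses
pose00068 BSA=0 Å², I/H=0/0
pose00064 BSA=300 Å², I/H=0/2
pose00011 BSA=0 Å², I/H=0/0
pose00102 BSA=11 Å², I/H=0/0
pose00089 BSA=0 Å², I/H=0/0
```

The tether keeps all 120 poses here because the toy domains are small, and
most representatives sit out of contact — the 8 Å perpendicular moves are
large relative to two short helices, so only one cluster's medoid keeps a
packed interface (300 Å² buried, two hydrophobic pairs). Stage counts are
written to the run log; the I/H column counts ionic/hydrophobic residue
pairs at each representative interface.

The same stages are available from the shell:

```bash
tetherdock fixtures rotamer_ensemble --seed 3 --out fx/
tetherdock couple fx/rotamers.pdb --seed 1 --out coupled/
tetherdock dock --static static.pdb --mobile mobile.pdb \
    --sites sites.yaml --seed 1 -n 10000 --out docked/
tetherdock triage --static static.pdb --mobile mobile.pdb \
    --manifest docked/poses.tsv --domains domains.yaml --out triaged/
```

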