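# adfsi — cannulation hemodynamics in aortic dissection, by planar FSI

During surgery for aortic dissection the cardiopulmonary-bypass pump can be
connected through the axillary artery alone (AC: all flow enters via the
brachiocephalic trunk) or through axillary and femoral cannulas together
(AFC: half the flow enters retrograde via the right common iliac artery).
With AC, the false lumen of the dissection — a pocket beside the true lumen,
fed by a large entry tear and drained only by a small re-entry tear —
pressurizes above the true lumen; the pressure difference ΔP = p_FL − p_TL
bows the intimal flap into the true lumen and chokes the celiac (CA) and
superior mesenteric (SMA) ostia: visceral malperfusion. `adfsi` models this
mechanism with a two-way coupled fluid–structure simulation on a planar
(mid-plane) analogue of a dissected aorta with nine branches, an entry tear
of 98.45 mm², a re-entry tear of 3.73 mm², and a 1 mm hyperelastic flap.

The package provides, as importable library modules:

- `materials` — third-order Ogden (Shore-20A silicone constants) and nearly
  incompressible neo-Hookean flap models, (E, ν) → (μ, d) conversion,
  plane-strain stress kernels;
- `geometry` — the parametric dissected-aorta description and a conforming
  fluid/solid mesher with named boundary tags;
- `fluid_solver` — steady/ALE incompressible Navier–Stokes (Taylor–Hood,
  Newton) with cannulation inflow and equal-pressure outlets;
- `solid_solver` — finite-strain statics and implicit dynamics of the
  clamped flap;
- `coupling` — the partitioned Dirichlet–Neumann loop with Aitken
  relaxation, mesh motion and a collapse gap guard;
- `postprocess` — branch-flow tables, ΔP at the CA/SMA stations, and the
  normalized true-lumen area A* = 100·A1/A0;
- `paper_tables` — verbatim plain-text replicas of the reference study's
  printed tables with a typo-flag layer and pinned checksums;
- `fixtures` — analytically anchored verification cases (Poiseuille,
  clamped beam, manufactured solutions, a miniature collapsible channel).

See `docs/methods.md` for the model, the planar reduction, and the
numerical choices.

## Worked example

Sweep both cannulation modes over 3–7 L/min with the neo-Hookean
Shore-20A flap (E = 0.732 MPa) on the reduced four-branch geometry:

```sh
$ adfsi sweep --flows 3,5,7 --scenarios AC,AFC --material nh0.732
  AC  3.0 L/min: dP(CA) = +0.00283 mmHg, A*(CA) =  94.79%  (converged=True)
  AC  5.0 L/min: dP(CA) = +0.00620 mmHg, A*(CA) =  91.55%  (converged=True)
  AC  7.0 L/min: dP(CA) = +0.01093 mmHg, A*(CA) =  88.74%  (converged=True)
 AFC  3.0 L/min: dP(CA) = +0.00110 mmHg, A*(CA) =  97.75%  (converged=True)
 AFC  5.0 L/min: dP(CA) = +0.00212 mmHg, A*(CA) =  96.13%  (converged=True)
 AFC  7.0 L/min: dP(CA) = +0.00345 mmHg, A*(CA) =  94.53%  (converged=True)
```

Reading the numbers: under AC the false-minus-true lumen pressure
difference at the celiac station grows with pump flow and the true lumen
narrows (A* falls from 94.8% to 88.7%); under AFC the pressure difference
stays ~3× smaller and the lumen stays open. A single case with its branch
flows (L/min, at the desk-scale operating flows — nominal flows times
0.06, see the methods note):

```sh
$ adfsi run --scenario AC --flow 4 --material nh0.732
                       BT      CA   CIA_L   CIA_R
scenario total_flow
AC       4.0         0.24  0.0216  0.1086  0.1098
CA: dP(FL-TL) = 0.580 Pa = 0.00435 mmHg, A* = 93.11%
converged=True collapse_limited=False
```

`adfsi tables --show T3` prints a packaged replica table;
`adfsi verify --suite all` runs the analytic verification fixtures.

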