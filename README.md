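# octomdm — semiautomatic tumor-board decision support

Multidisciplinary team meetings (MDMs, tumor boards) are the standard forum
for cancer treatment decisions, but they are expensive and crowded: median
discussion time per case can fall to a couple of minutes. Many cases are
routine — their guideline-conform treatment can be derived mechanically from
a short structured file — while the scarce face-to-face time is best spent on
the genuinely complex ones. `octomdm` implements that triage for upper
aerodigestive tract (head and neck) cancers:

- **Case model.** A standard patient file: tumor sublocation (glottic or
  supraglottic larynx, nasopharynx, oral tongue, floor of mouth, oropharynx,
  base of tongue, hypopharynx), TNM stage, histology (squamous/epidermoid
  carcinoma or UCNT), per-modality feasibility (surgery, radiation,
  chemotherapy), relapse status, and free-text poor-prognosis factors.
- **Decision engine.** An editable NCCN-style rule table maps
  (sublocation, stage class) to candidate regimens; stage class is *early*
  (T1–T2 N0 M0), *locally advanced* (any other M0), or *metastatic* (M1).
  Candidates are filtered by feasibility. Relapse, metastatic disease, or an
  empty feasible set escalate the case to a face-to-face MDM instead.
- **Review workflow.** The five consultant roles (otolaryngologist,
  oncologist, radiotherapist, radiologist, pathologist) vote on the proposal
  within a 15-day window; a unanimous regimen validates the case, any split
  or any in-person request escalates it. Residents submit cases, may edit
  only their own drafts, and see only their own final reports. An internal
  mailing primitive records imaging/pathology review requests.
- **Agreement statistics.** Decision strings ("Radiation + chemotherapy",
  "Surgery ± radiation", "Face-to-face MDM") are canonicalized, and
  automatic-vs-expert agreement is scored with unweighted Cohen's
  κ = (p_o − p_e)/(1 − p_e), with Landis–Koch interpretation bands.

Ten fictitious benchmark cases ship with the package, together with the
automatic and blinded-expert decision strings, plus a seeded synthetic case
generator for property testing at scale.

## Worked example

```python
from octomdm import (
    decide, load_table1_fixtures, canonicalize, canonicalize_decision_set,
    cohen_kappa,
)

fixtures = load_table1_fixtures()          # the 10 packaged benchmark cases
case = fixtures[0].case                    # glottic larynx, T1N0M0, all feasible
print(decide(case))                        # -> Radiation or Surgery

pairs = [
    (canonicalize_decision_set(decide(f.case)), canonicalize(f.expected_expert))
    for f in fixtures
]
result = cohen_kappa(pairs)
print(result.to_dict())
```

prints

```
Radiation or Surgery
{'p_observed': 0.7, 'p_expected': 0.2, 'kappa': 0.6249999999999999,
 'n_items': 10, 'label': 'substantial'}
```

i.e. the engine and the blinded expert give the identical canonical decision
on 7 of the 10 benchmark cases (the expert narrows the option set on the
other three), expected chance agreement from the marginals is 0.20, and the
chance-corrected agreement κ = 0.625 falls in the "substantial" band.

The same is available from the shell:

```bash
octomdm fixtures                      # list the packaged cases
octomdm decide case.json              # one case -> JSON + table dialect
octomdm batch roster.csv              # a whole roster
octomdm simulate out.csv --n 100 --seed 7
octomdm kappa pairs.csv               # decision_a,decision_b columns
octomdm workflow submit roster/ case.json --now 2023-01-01T09:00
```

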