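{
 "version": 1,
 "id": "amp_chain",
 "description": "chain with a coefficient-2 step",
 "metabolites": [
  {
   "id": "A",
   "name": "A",
   "formula": "",
   "charge": null,
   "compartment": "c"
  },
  {
   "id": "B",
   "name": "B",
   "formula": "",
   "charge": null,
   "compartment": "c"
  },
  {
   "id": "D",
   "name": "D",
   "formula": "",
   "charge": null,
   "compartment": "c"
  }
 ],
 "genes": [
  {
   "id": "g1",
   "name": "",
   "functional": true
  },
  {
   "id": "g2",
   "name": "",
   "functional": true
  }
 ],
 "reactions": [
  {
   "id": "EX_A",
   "name": "",
   "stoichiometry": {
    "A": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 10.0,
   "objective_coefficient": 0.0,
   "gpr": "",
   "subsystem": ""
  },
  {
   "id": "R1",
   "name": "",
   "stoichiometry": {
    "A": -1.0,
    "B": 2.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gpr": "g1",
   "subsystem": ""
  },
  {
   "id": "R2",
   "name": "",
   "stoichiometry": {
    "B": -1.0,
    "D": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gpr": "g2",
   "subsystem": ""
  },
  {
   "id": "EX_D",
   "name": "",
   "stoichiometry": {
    "D": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 1.0,
   "gpr": "",
   "subsystem": ""
  }
 ],
 "media": {}
}
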