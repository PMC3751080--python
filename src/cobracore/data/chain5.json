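{
 "version": 1,
 "id": "chain5",
 "description": "linear chain of 5 reactions",
 "metabolites": [
  {
   "id": "M0",
   "name": "M0",
   "formula": "",
   "charge": null,
   "compartment": "c"
  },
  {
   "id": "M1",
   "name": "M1",
   "formula": "",
   "charge": null,
   "compartment": "c"
  },
  {
   "id": "M2",
   "name": "M2",
   "formula": "",
   "charge": null,
   "compartment": "c"
  },
  {
   "id": "M3",
   "name": "M3",
   "formula": "",
   "charge": null,
   "compartment": "c"
  },
  {
   "id": "M4",
   "name": "M4",
   "formula": "",
   "charge": null,
   "compartment": "c"
  },
  {
   "id": "M5",
   "name": "M5",
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
  },
  {
   "id": "g3",
   "name": "",
   "functional": true
  },
  {
   "id": "g4",
   "name": "",
   "functional": true
  },
  {
   "id": "g5",
   "name": "",
   "functional": true
  }
 ],
 "reactions": [
  {
   "id": "EX_src",
   "name": "",
   "stoichiometry": {
    "M0": 1.0
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
    "M0": -1.0,
    "M1": 1.0
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
    "M1": -1.0,
    "M2": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gpr": "g2",
   "subsystem": ""
  },
  {
   "id": "R3",
   "name": "",
   "stoichiometry": {
    "M2": -1.0,
    "M3": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gpr": "g3",
   "subsystem": ""
  },
  {
   "id": "R4",
   "name": "",
   "stoichiometry": {
    "M3": -1.0,
    "M4": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gpr": "g4",
   "subsystem": ""
  },
  {
   "id": "R5",
   "name": "",
   "stoichiometry": {
    "M4": -1.0,
    "M5": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gpr": "g5",
   "subsystem": ""
  },
  {
   "id": "EX_sink",
   "name": "",
   "stoichiometry": {
    "M5": -1.0
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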