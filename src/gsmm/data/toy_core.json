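{
 "schema": "gsmm-model-1",
 "id": "toy_core",
 "genome_orf_count": null,
 "compartments": {
  "e": "e",
  "c": "c"
 },
 "objective": "BIOMASS",
 "metabolites": [
  {
   "id": "glc_e",
   "name": "glc_e",
   "compartment": "e",
   "formula": null,
   "charge": null
  },
  {
   "id": "glc_c",
   "name": "glc_c",
   "compartment": "c",
   "formula": null,
   "charge": null
  },
  {
   "id": "pyr_c",
   "name": "pyr_c",
   "compartment": "c",
   "formula": null,
   "charge": null
  },
  {
   "id": "prod_c",
   "name": "prod_c",
   "compartment": "c",
   "formula": null,
   "charge": null
  },
  {
   "id": "prod_e",
   "name": "prod_e",
   "compartment": "e",
   "formula": null,
   "charge": null
  },
  {
   "id": "biomass_c",
   "name": "biomass_c",
   "compartment": "c",
   "formula": null,
   "charge": null
  }
 ],
 "reactions": [
  {
   "id": "EX_glc",
   "name": "EX_glc",
   "stoichiometry": {
    "glc_e": -1.0
   },
   "lower_bound": -10.0,
   "upper_bound": 1000.0,
   "gpr": null,
   "subsystem": "Exchange"
  },
  {
   "id": "GLCt",
   "name": "GLCt",
   "stoichiometry": {
    "glc_e": -1.0,
    "glc_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "g_transp",
   "subsystem": "Transport"
  },
  {
   "id": "GLY",
   "name": "GLY",
   "stoichiometry": {
    "glc_c": -1.0,
    "pyr_c": 2.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": [
    "or",
    [
     "g_gly1",
     "g_gly2"
    ]
   ],
   "subsystem": "Central carbon"
  },
  {
   "id": "BIOMASS",
   "name": "BIOMASS",
   "stoichiometry": {
    "pyr_c": -3.0,
    "biomass_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": null,
   "subsystem": "Biomass"
  },
  {
   "id": "EX_biomass",
   "name": "EX_biomass",
   "stoichiometry": {
    "biomass_c": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": null,
   "subsystem": "Exchange"
  },
  {
   "id": "PROD",
   "name": "PROD",
   "stoichiometry": {
    "pyr_c": -1.0,
    "prod_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "g_prod",
   "subsystem": "Product"
  },
  {
   "id": "PRODt",
   "name": "PRODt",
   "stoichiometry": {
    "prod_c": -1.0,
    "prod_e": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": null,
   "subsystem": "Transport"
  },
  {
   "id": "EX_prod",
   "name": "EX_prod",
   "stoichiometry": {
    "prod_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": null,
   "subsystem": "Exchange"
  }
 ]
}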