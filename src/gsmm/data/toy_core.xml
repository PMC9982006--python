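<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2" level="3" version="1" fbc:required="false">
  <model id="toy_core" fbc:strict="true">
    <listOfCompartments>
      <compartment id="e" name="e" constant="true"/>
      <compartment id="c" name="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="glc_e" name="glc_e" compartment="e" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="glc_c" name="glc_c" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="pyr_c" name="pyr_c" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="prod_c" name="prod_c" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="prod_e" name="prod_e" compartment="e" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="biomass_c" name="biomass_c" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="fb_0" value="-10" constant="true"/>
      <parameter id="fb_1" value="1000" constant="true"/>
      <parameter id="fb_2" value="0" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="EX_glc" name="EX_glc" reversible="true" fast="false" fbc:lowerFluxBound="fb_0" fbc:upperFluxBound="fb_1">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>SUBSYSTEM: Exchange</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="glc_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="GLCt" name="GLCt" reversible="false" fast="false" fbc:lowerFluxBound="fb_2" fbc:upperFluxBound="fb_1">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>SUBSYSTEM: Transport</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="glc_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="glc_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:geneProductRef fbc:geneProduct="g_transp"/>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="GLY" name="GLY" reversible="false" fast="false" fbc:lowerFluxBound="fb_2" fbc:upperFluxBound="fb_1">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>SUBSYSTEM: Central carbon</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="glc_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="pyr_c" stoichiometry="2" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:or>
            <fbc:geneProductRef fbc:geneProduct="g_gly1"/>
            <fbc:geneProductRef fbc:geneProduct="g_gly2"/>
          </fbc:or>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="BIOMASS" name="BIOMASS" reversible="false" fast="false" fbc:lowerFluxBound="fb_2" fbc:upperFluxBound="fb_1">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>SUBSYSTEM: Biomass</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="pyr_c" stoichiometry="3" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="biomass_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="EX_biomass" name="EX_biomass" reversible="false" fast="false" fbc:lowerFluxBound="fb_2" fbc:upperFluxBound="fb_1">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>SUBSYSTEM: Exchange</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="biomass_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="PROD" name="PROD" reversible="false" fast="false" fbc:lowerFluxBound="fb_2" fbc:upperFluxBound="fb_1">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>SUBSYSTEM: Product</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="pyr_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="prod_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:geneProductRef fbc:geneProduct="g_prod"/>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="PRODt" name="PRODt" reversible="false" fast="false" fbc:lowerFluxBound="fb_2" fbc:upperFluxBound="fb_1">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>SUBSYSTEM: Transport</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="prod_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="prod_e" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="EX_prod" name="EX_prod" reversible="false" fast="false" fbc:lowerFluxBound="fb_2" fbc:upperFluxBound="fb_1">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>SUBSYSTEM: Exchange</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="prod_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="BIOMASS" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
    <fbc:listOfGeneProducts>
      <fbc:geneProduct fbc:id="g_gly1" fbc:label="g_gly1"/>
      <fbc:geneProduct fbc:id="g_gly2" fbc:label="g_gly2"/>
      <fbc:geneProduct fbc:id="g_prod" fbc:label="g_prod"/>
      <fbc:geneProduct fbc:id="g_transp" fbc:label="g_transp"/>
    </fbc:listOfGeneProducts>
  </model>
</sbml>
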