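<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2" level="3" version="1" fbc:required="false">
  <model id="toy9" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="B" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="C" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="D" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="E" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="bnd_0" value="-10" constant="true"/>
      <parameter id="bnd_1" value="1000" constant="true"/>
      <parameter id="bnd_2" value="0" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="EX_A" reversible="true" fast="false" fbc:lowerFluxBound="bnd_0" fbc:upperFluxBound="bnd_1">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="R1" reversible="false" fast="false" fbc:lowerFluxBound="bnd_2" fbc:upperFluxBound="bnd_1">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:geneProductRef fbc:geneProduct="g1"/>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="R2" reversible="false" fast="false" fbc:lowerFluxBound="bnd_2" fbc:upperFluxBound="bnd_1">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="C" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:or>
            <fbc:geneProductRef fbc:geneProduct="g2"/>
            <fbc:geneProductRef fbc:geneProduct="g3"/>
          </fbc:or>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="R3" reversible="false" fast="false" fbc:lowerFluxBound="bnd_2" fbc:upperFluxBound="bnd_1">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="D" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:and>
            <fbc:geneProductRef fbc:geneProduct="g4"/>
            <fbc:geneProductRef fbc:geneProduct="g5"/>
          </fbc:and>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="BIOMASS" reversible="false" fast="false" fbc:lowerFluxBound="bnd_2" fbc:upperFluxBound="bnd_1">
        <listOfReactants>
          <speciesReference species="C" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="EX_D" reversible="false" fast="false" fbc:lowerFluxBound="bnd_2" fbc:upperFluxBound="bnd_1">
        <listOfReactants>
          <speciesReference species="D" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="R5" reversible="false" fast="false" fbc:lowerFluxBound="bnd_2" fbc:upperFluxBound="bnd_1">
        <listOfReactants>
          <speciesReference species="C" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="E" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:geneProductRef fbc:geneProduct="g6"/>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="EX_E" reversible="false" fast="false" fbc:lowerFluxBound="bnd_2" fbc:upperFluxBound="bnd_1">
        <listOfReactants>
          <speciesReference species="E" stoichiometry="1" constant="true"/>
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
      <fbc:geneProduct fbc:id="g1" fbc:label="g1"/>
      <fbc:geneProduct fbc:id="g2" fbc:label="g2"/>
      <fbc:geneProduct fbc:id="g3" fbc:label="g3"/>
      <fbc:geneProduct fbc:id="g4" fbc:label="g4"/>
      <fbc:geneProduct fbc:id="g5" fbc:label="g5"/>
      <fbc:geneProduct fbc:id="g6" fbc:label="g6"/>
    </fbc:listOfGeneProducts>
  </model>
</sbml>
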