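<?xml version="1.0" encoding="UTF-8"?>
<!-- Simplified medication-schedule dialect: one <row> per drug with the
     analysed subset of the national plan's fields. The scheme attribute is
     the morning-noon-evening-night quadruple (e.g. "1-0-1-0") or free text. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">
  <xs:element name="medicationSchedule">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="row" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="pzn" type="xs:string"/>
            <xs:attribute name="name" type="xs:string"/>
            <xs:attribute name="ingredient" type="xs:string"/>
            <xs:attribute name="form" type="xs:string"/>
            <xs:attribute name="strength" type="xs:string"/>
            <xs:attribute name="scheme" type="xs:string"/>
            <xs:attribute name="unit" type="xs:string"/>
            <xs:attribute name="instructions" type="xs:string"/>
            <xs:attribute name="indication" type="xs:string"/>
            <xs:attribute name="prn" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="patient" type="xs:string"/>
      <xs:attribute name="issued" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
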