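<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="nodeKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="scalar"/>
      <xs:enumeration value="container"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="subjectKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="patient_summary"/>
      <xs:enumeration value="plan_detailed"/>
      <xs:enumeration value="structure_set_detailed"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="node">
    <xs:complexType mixed="true">
      <xs:sequence>
        <xs:element ref="node" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="key" type="xs:string" use="required"/>
      <xs:attribute name="kind" type="nodeKind" use="required"/>
      <xs:attribute name="ordinal" type="xs:nonNegativeInteger"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="snapshot">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="node"/>
      </xs:sequence>
      <xs:attribute name="schema_version" type="xs:string" use="required"/>
      <xs:attribute name="subject_kind" type="subjectKind" use="required"/>
      <xs:attribute name="subject_path" type="xs:string" use="required"/>
      <xs:attribute name="acquired_at" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
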