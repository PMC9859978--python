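<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="changeKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="added"/>
      <xs:enumeration value="removed"/>
      <xs:enumeration value="modified"/>
      <xs:enumeration value="renamed"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="snapshotRef">
    <xs:attribute name="subject_kind" type="xs:string" use="required"/>
    <xs:attribute name="subject_path" type="xs:string" use="required"/>
    <xs:attribute name="acquired_at" type="xs:string" use="required"/>
    <xs:attribute name="source" type="xs:string"/>
  </xs:complexType>

  <xs:element name="comparison_report">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="before" type="snapshotRef"/>
        <xs:element name="after" type="snapshotRef"/>
        <xs:element name="counts">
          <xs:complexType>
            <xs:attribute name="added" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="removed" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="modified" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="renamed" type="xs:nonNegativeInteger" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="differences">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="difference" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="path" type="xs:string" use="required"/>
                  <xs:attribute name="change" type="changeKind" use="required"/>
                  <xs:attribute name="before" type="xs:string"/>
                  <xs:attribute name="after" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="schema_version" type="xs:string" use="required"/>
      <xs:attribute name="clean" type="xs:boolean" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
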