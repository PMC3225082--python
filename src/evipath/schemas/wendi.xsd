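<?xml version="1.0" encoding="UTF-8"?>
<!-- Evidence-document dialect for one query compound: similar compounds
     with Tanimoto similarities, grouped into the four evidence channels. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">

  <xs:simpleType name="similarity">
    <xs:restriction base="xs:decimal">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="1"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="groupName">
    <xs:restriction base="xs:string">
      <xs:enumeration value="ActiveBioassay"/>
      <xs:enumeration value="CTD"/>
      <xs:enumeration value="Chembl"/>
      <xs:enumeration value="Literature"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="wendi">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="group" minOccurs="0" maxOccurs="4">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="record" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:choice>
                    <xs:element name="bioassay">
                      <xs:complexType>
                        <xs:attribute name="id" type="xs:string" use="required"/>
                        <xs:attribute name="description" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="disease">
                      <xs:complexType>
                        <xs:attribute name="id" type="xs:string" use="required"/>
                        <xs:attribute name="provenance" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="target">
                      <xs:complexType>
                        <xs:attribute name="gene" type="xs:string" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="article">
                      <xs:complexType>
                        <xs:attribute name="pmid" type="xs:string" use="required"/>
                        <xs:attribute name="title" type="xs:string"/>
                        <xs:attribute name="abstract" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:choice>
                  <xs:attribute name="compound" type="xs:string" use="required"/>
                  <xs:attribute name="similarity" type="similarity" use="required"/>
                  <xs:attribute name="name" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="name" type="groupName" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="query-id" type="xs:string" use="required"/>
      <xs:attribute name="smiles" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
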